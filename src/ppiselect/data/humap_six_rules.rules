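# Published six-rule classifier for hu.MAP protein-pair features.
# Ordered, first match wins; anything unmatched is a positive (interacting) pair.
IF (neg_ln_pval <= 3.622) and (hein_neg_ln_pval <= 3.328) THEN negative
IF (hein_neg_ln_pval <= 6.955) and (Hs_G166_1104_pq_euc <= 0) and (neg_ln_pval <= 3.994) THEN negative
IF (hein_neg_ln_pval <= 6.960) and (neg_ln_pval <= 5.780) and (Hs_G166_1104_pq_euc <= 0) and (pair_count >= 2) THEN negative
IF (hein_neg_ln_pval <= 3.033) and (Hs_G166_1104_pq_euc <= 0) and (pair_count <= 3) and (neg_ln_pval <= 7.272) THEN negative
IF (hein_neg_ln_pval <= 0) and (Hs_G166_1104_pq_euc <= 0) and (pair_count <= 3) and (neg_ln_pval <= 8.611) THEN negative
DEFAULT positive
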