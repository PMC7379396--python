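"""Direction-cosine identity distributions of the two splits.

High identities between pairs would mean redundant rows and an easy
classification task; the expected picture is most mass well below 0.5.
"""

from ppiselect import identity_histogram, read_table

from common import DATA, RESULTS

for split in ("train", "test"):
    table = read_table(DATA / f"{split}.csv")
    hist = identity_histogram(table, "all_vs_all")
    hist.to_frame().to_csv(RESULTS / f"identity_{split}.tsv", sep="\t", index=False)
    below = hist.counts[:15].sum() / hist.n_pairs
    print(f"{split}: {hist.n_pairs} pairs compared, {below:.1%} with identity < 0.5")
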