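"""RIPPER rule induction and an interpreter for ordered IF-THEN rule sets.

A rule set is an ordered list of conjunctive threshold rules with
first-match-wins semantics and a default class when no rule fires —
exactly the shape of the published six-rule classifier for the hu.MAP
protein-pair feature space, which ships with the package as a text
fixture (:func:`reference_ruleset`).

The learner follows Cohen's RIPPER scheme: classes are processed in
increasing frequency order; rules are grown greedily by FOIL information
gain on a grow split, pruned to maximize (p - n)/(p + n) on a prune
split, and rule addition stops when a rule's prune-set error reaches 50%
or the description length of the rule set exceeds the best seen so far by
a slack (default 64 bits).  Optimization rounds re-grow each rule on its
residual data and keep whichever variant makes fewer training errors.
The description-length encoding is a simplified MDL (condition-count
prior plus binomial exception coding).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .dataset_io import NEGATIVE, POSITIVE, FeatureTable
from .errors import RuleResolutionError, RuleSyntaxError, ValidationError
from .evaluation import Predictor, ScoredPredictions, derive_seed

_CLASS_NAMES = {0: NEGATIVE, 1: POSITIVE}
_CLASS_CODES = {NEGATIVE: 0, POSITIVE: 1}


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str  # "<=" or ">="
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("<=", ">="):
            raise ValidationError(f"operator must be '<=' or '>=', got {self.op!r}")

    def holds(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values)
        return values <= self.threshold if self.op == "<=" else values >= self.threshold

    def __str__(self) -> str:
        return f"({self.feature} {self.op} {self.threshold:g})"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    consequent: int  # class code: 1 positive, 0 negative
    coverage: tuple[int, int] | None = None  # (correct, wrong) on training data

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValidationError("a rule needs at least one condition (use the default)")

    def __str__(self) -> str:
        body = " and ".join(str(c) for c in self.conditions)
        return f"IF {body} THEN {_CLASS_NAMES[self.consequent]}"


@dataclass(frozen=True)
class RuleSet:
    rules: tuple[Rule, ...]
    default: int
    default_coverage: tuple[int, int] | None = None

    @property
    def n_rules(self) -> int:
        """Rule count including the default rule."""
        return len(self.rules) + 1

    @property
    def features(self) -> list[str]:
        seen: dict[str, None] = {}
        for rule in self.rules:
            for cond in rule.conditions:
                seen.setdefault(cond.feature, None)
        return list(seen)

    def __str__(self) -> str:
        lines = [str(r) for r in self.rules]
        lines.append(f"DEFAULT {_CLASS_NAMES[self.default]}")
        return "\n".join(lines)


@dataclass(frozen=True)
class RipperConfig:
    seed: int = 0
    prune_fraction: float = 1 / 3
    optimize_rounds: int = 2
    dl_slack_bits: float = 64.0
    min_coverage: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.prune_fraction < 1:
            raise ValidationError("prune_fraction must be in (0, 1)")
        if self.optimize_rounds < 0:
            raise ValidationError("optimize_rounds must be >= 0")
        if self.min_coverage < 1:
            raise ValidationError("min_coverage must be >= 1")


# ---------------------------------------------------------------- interpreter


def _match_matrix(rs: RuleSet, X: np.ndarray, name_to_col: dict[str, int]) -> np.ndarray:
    missing = [f for f in rs.features if f not in name_to_col]
    if missing:
        raise RuleResolutionError(f"rule features absent from table: {missing}")
    n = len(X)
    matches = np.zeros((len(rs.rules), n), dtype=bool)
    for i, rule in enumerate(rs.rules):
        m = np.ones(n, dtype=bool)
        for cond in rule.conditions:
            m &= cond.holds(X[:, name_to_col[cond.feature]])
        matches[i] = m
    return matches


def apply_ruleset(rs: RuleSet, table: FeatureTable) -> ScoredPredictions:
    """Classify every row by the first rule whose conjunction holds.

    The positive-class score is the Laplace-corrected training precision
    of the firing rule when coverage statistics are available, else a
    hard 1/0.
    """
    name_to_col = {n: j for j, n in enumerate(table.feature_names)}
    matches = _match_matrix(rs, table.X, name_to_col)
    n = table.n_rows
    y_pred = np.full(n, rs.default, dtype=np.int8)
    scores = np.full(n, _positive_score(rs.default, rs.default_coverage))
    unassigned = np.ones(n, dtype=bool)
    for i, rule in enumerate(rs.rules):
        fire = matches[i] & unassigned
        y_pred[fire] = rule.consequent
        scores[fire] = _positive_score(rule.consequent, rule.coverage)
        unassigned &= ~matches[i]
    return ScoredPredictions(table.y, scores, y_pred)


def _positive_score(consequent: int, coverage: tuple[int, int] | None) -> float:
    if coverage is None:
        return float(consequent)
    p, n = coverage
    laplace = (p + 1) / (p + n + 2)
    return laplace if consequent == 1 else 1.0 - laplace


def ruleset_predictor(rs: RuleSet, feature_names: Sequence[str]) -> Predictor:
    """Bind a rule set to a column layout, returning a matrix predictor."""
    name_to_col = {n: j for j, n in enumerate(feature_names)}

    def predict(X: np.ndarray) -> ScoredPredictions:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        matches = _match_matrix(rs, X, name_to_col)
        y_pred = np.full(len(X), rs.default, dtype=np.int8)
        scores = np.full(len(X), _positive_score(rs.default, rs.default_coverage))
        unassigned = np.ones(len(X), dtype=bool)
        for i, rule in enumerate(rs.rules):
            fire = matches[i] & unassigned
            y_pred[fire] = rule.consequent
            scores[fire] = _positive_score(rule.consequent, rule.coverage)
            unassigned &= ~matches[i]
        return ScoredPredictions(None, scores, y_pred)

    return predict


# ------------------------------------------------------------- text format


_RULE_RE = re.compile(r"^IF\s+(.+)\s+THEN\s+(\w+)$")
_COND_RE = re.compile(r"^\(\s*(\S+)\s*(<=|>=)\s*([-+]?[0-9.eE]+)\s*\)$")
_DEFAULT_RE = re.compile(r"^DEFAULT\s+(\w+)$")


def parse_ruleset(text: str) -> RuleSet:
    """Parse the one-rule-per-line text grammar.

    ``IF (<feature> <op> <number>) [and (...)] THEN <class>`` lines,
    terminated by a single ``DEFAULT <class>`` line.
    """
    rules: list[Rule] = []
    default: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if default is not None:
            raise RuleSyntaxError("content after DEFAULT line", line=lineno)
        dm = _DEFAULT_RE.match(line)
        if dm:
            default = _parse_class(dm.group(1), lineno)
            continue
        rm = _RULE_RE.match(line)
        if not rm:
            raise RuleSyntaxError(f"unparseable rule: {line!r}", line=lineno)
        conds = []
        for part in re.split(r"\s+and\s+", rm.group(1)):
            cm = _COND_RE.match(part.strip())
            if not cm:
                raise RuleSyntaxError(f"unparseable condition: {part.strip()!r}", line=lineno)
            conds.append(Condition(cm.group(1), cm.group(2), float(cm.group(3))))
        rules.append(Rule(tuple(conds), _parse_class(rm.group(2), lineno)))
    if default is None:
        raise RuleSyntaxError("missing DEFAULT line")
    return RuleSet(tuple(rules), default)


def _parse_class(word: str, lineno: int) -> int:
    code = _CLASS_CODES.get(word.lower())
    if code is None:
        raise RuleSyntaxError(f"unknown class {word!r}", line=lineno)
    return code


def format_ruleset(rs: RuleSet) -> str:
    return str(rs) + "\n"


def reference_ruleset() -> RuleSet:
    """The published six-rule classifier for hu.MAP protein-pair features.

    Five ordered rules predict the negative (non-interacting) class from
    thresholds on co-purification enrichment p-value scores
    (``neg_ln_pval``, ``hein_neg_ln_pval``), a charge-distribution
    distance (``Hs_G166_1104_pq_euc``) and an observation count
    (``pair_count``); anything else defaults to positive (interacting).
    """
    text = resources.files("ppiselect.data").joinpath("humap_six_rules.rules").read_text()
    return parse_ruleset(text)


# ---------------------------------------------------------------- learning


def _foil_best_condition(
    X: np.ndarray, y: np.ndarray, covered: np.ndarray, target: int
):
    """Best (feature, op, threshold) by FOIL gain on the covered rows, or None."""
    rows = np.flatnonzero(covered)
    yc = (y[rows] == target).astype(np.float64)
    p0, n0 = yc.sum(), len(rows) - yc.sum()
    if p0 == 0:
        return None
    base = math.log2(p0 / (p0 + n0))
    best_gain, best = 1e-9, None
    for f in range(X.shape[1]):
        v = X[rows, f]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], yc[order]
        distinct = np.flatnonzero(vs[1:] > vs[:-1]) + 1  # split positions
        if not distinct.size:
            continue
        cum = np.cumsum(ys)
        thr = (vs[distinct - 1] + vs[distinct]) / 2
        # op "<=": keep the first i rows
        p1 = cum[distinct - 1]
        n1 = distinct - p1
        gain_le = _foil_gain(p1, n1, base)
        # op ">=": keep rows from i on
        p1g = p0 - p1
        n1g = (len(rows) - distinct) - p1g
        gain_ge = _foil_gain(p1g, n1g, base)
        for ops, gains in (("<=", gain_le), (">=", gain_ge)):
            j = int(np.argmax(gains))
            if gains[j] > best_gain:
                best_gain = float(gains[j])
                best = (f, ops, float(thr[j]))
    return best


def _foil_gain(p1: np.ndarray, n1: np.ndarray, base: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = p1 * (np.log2(np.where(p1 > 0, p1 / (p1 + n1), 1.0)) - base)
    return np.where(p1 > 0, gain, -np.inf)


def _rule_covers(rule_conds: Sequence[Condition], X: np.ndarray, cols: dict[str, int]) -> np.ndarray:
    m = np.ones(len(X), dtype=bool)
    for cond in rule_conds:
        m &= cond.holds(X[:, cols[cond.feature]])
    return m


def _grow_rule(
    X: np.ndarray, y: np.ndarray, target: int, feature_names: Sequence[str]
) -> tuple[Condition, ...] | None:
    covered = np.ones(len(X), dtype=bool)
    conds: list[Condition] = []
    while True:
        rows = y[covered]
        if not covered.any() or not (rows != target).any():
            break  # no negatives covered
        best = _foil_best_condition(X, y, covered, target)
        if best is None:
            break
        f, op, thr = best
        cond = Condition(feature_names[f], op, thr)
        conds.append(cond)
        covered &= cond.holds(X[:, f])
    return tuple(conds) if conds else None


def _prune_rule(
    conds: tuple[Condition, ...],
    X: np.ndarray,
    y: np.ndarray,
    target: int,
    cols: dict[str, int],
) -> tuple[Condition, ...]:
    """Drop a final sequence of conditions maximizing (p - n)/(p + n) on prune data."""
    best_conds, best_score = conds, _prune_score(conds, X, y, target, cols)
    for keep in range(len(conds) - 1, 0, -1):
        cand = conds[:keep]
        score = _prune_score(cand, X, y, target, cols)
        if score > best_score:  # strict: ties keep the longer rule
            best_conds, best_score = cand, score
    return best_conds


def _prune_score(
    conds: Sequence[Condition], X: np.ndarray, y: np.ndarray, target: int, cols: dict[str, int]
) -> float:
    m = _rule_covers(conds, X, cols)
    p = int((y[m] == target).sum())
    n = int(m.sum()) - p
    return (p - n) / (p + n) if p + n else -math.inf


def _ruleset_dl(
    rules: list[tuple[Condition, ...]],
    X: np.ndarray,
    y: np.ndarray,
    target: int,
    cols: dict[str, int],
    n_conditions_space: float,
) -> float:
    """Simplified MDL: condition-count prior per rule + binomial exception coding."""
    theory = 0.0
    for conds in rules:
        k = len(conds)
        theory += 0.5 * (math.log2(k + 1) + k * math.log2(max(n_conditions_space, 2.0)))
    covered = np.zeros(len(X), dtype=bool)
    for conds in rules:
        covered |= _rule_covers(conds, X, cols)
    is_target = y == target
    fp = int((covered & ~is_target).sum())
    fn = int((~covered & is_target).sum())
    n_cov, n_unc = int(covered.sum()), int((~covered).sum())
    return theory + _log2_binom(n_cov, fp) + _log2_binom(n_unc, fn)


def _log2_binom(n: int, k: int) -> float:
    if n <= 0 or k <= 0 or k > n:
        return 0.0
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / math.log(2))


def ripper_fit(table: FeatureTable, cfg: RipperConfig = RipperConfig()) -> RuleSet:
    """Learn an ordered rule set for the minority class; majority is the default."""
    if table.n_positive == 0 or table.n_negative == 0:
        raise ValidationError("both classes must be present")
    X, y = table.X, table.y
    cols = {n: j for j, n in enumerate(table.feature_names)}
    names = table.feature_names
    # classes in increasing frequency order; the last (majority) becomes default
    target = 1 if table.n_positive <= table.n_negative else 0
    default = 1 - target

    n_cond_space = float(
        sum(2 * max(len(np.unique(X[:, f])) - 1, 1) for f in range(X.shape[1]))
    )
    remaining = np.arange(table.n_rows)
    rules: list[tuple[Condition, ...]] = []
    best_dl = _ruleset_dl([], X, y, target, cols, n_cond_space)
    iteration = 0
    while (y[remaining] == target).any():
        grow_idx, prune_idx = _grow_prune_split(
            y[remaining], cfg.prune_fraction, derive_seed(cfg.seed, "split", iteration)
        )
        iteration += 1
        Xg, yg = X[remaining[grow_idx]], y[remaining[grow_idx]]
        Xp, yp = X[remaining[prune_idx]], y[remaining[prune_idx]]
        conds = _grow_rule(Xg, yg, target, names)
        if conds is None:
            break
        conds = _prune_rule(conds, Xp, yp, target, cols)
        # reject rules that are wrong at least half the time on the prune split
        mp = _rule_covers(conds, Xp, cols)
        p = int((yp[mp] == target).sum())
        nwrong = int(mp.sum()) - p
        if mp.any() and nwrong >= p:
            break
        mg = _rule_covers(conds, Xg, cols)
        if int((yg[mg] == target).sum()) < cfg.min_coverage:
            break
        dl = _ruleset_dl(rules + [conds], X[remaining], y[remaining], target, cols, n_cond_space)
        if dl > best_dl + cfg.dl_slack_bits:
            break
        best_dl = min(best_dl, dl)
        rules.append(conds)
        covered = _rule_covers(conds, X[remaining], cols)
        remaining = remaining[~covered]
        if not remaining.size:
            break

    for rnd in range(cfg.optimize_rounds):
        rules = _optimize_pass(rules, X, y, target, names, cols, cfg, rnd)

    return _finalize(rules, X, y, target, default, cols)


def _grow_prune_split(y: np.ndarray, prune_fraction: float, seed: int):
    """Seeded class-stratified split into grow and prune index sets."""
    rng = np.random.default_rng(seed)
    grow, prune = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        cut = max(1, int(round(len(idx) * (1 - prune_fraction))))
        grow.append(idx[:cut])
        prune.append(idx[cut:])
    g = np.sort(np.concatenate(grow))
    p = np.sort(np.concatenate(prune)) if any(len(a) for a in prune) else g
    return g, p if len(p) else g


def _total_errors(
    rules: list[tuple[Condition, ...]], X, y, target, default, cols
) -> int:
    rs = _finalize(rules, X, y, target, default, cols)
    pred = np.full(len(X), default, dtype=np.int8)
    unassigned = np.ones(len(X), dtype=bool)
    for rule in rs.rules:
        m = _rule_covers(rule.conditions, X, cols) & unassigned
        pred[m] = rule.consequent
        unassigned &= ~m
    return int((pred != y).sum())


def _optimize_pass(
    rules: list[tuple[Condition, ...]], X, y, target, names, cols, cfg: RipperConfig, rnd: int
) -> list[tuple[Condition, ...]]:
    default = 1 - target
    for i in range(len(rules)):
        others = rules[:i]
        covered = np.zeros(len(X), dtype=bool)
        for conds in others:
            covered |= _rule_covers(conds, X, cols)
        residual = np.flatnonzero(~covered)
        if not (y[residual] == target).any():
            continue
        gi, pi = _grow_prune_split(
            y[residual], cfg.prune_fraction, derive_seed(cfg.seed, "optimize", rnd, i)
        )
        replacement = _grow_rule(X[residual[gi]], y[residual[gi]], target, names)
        if replacement is None:
            continue
        replacement = _prune_rule(replacement, X[residual[pi]], y[residual[pi]], target, cols)
        candidate = rules[:i] + [replacement] + rules[i + 1 :]
        if _total_errors(candidate, X, y, target, default, cols) < _total_errors(
            rules, X, y, target, default, cols
        ):
            rules = candidate
    return rules


def _finalize(
    rules: list[tuple[Condition, ...]], X, y, target, default, cols
) -> RuleSet:
    out: list[Rule] = []
    unassigned = np.ones(len(X), dtype=bool)
    for conds in rules:
        m = _rule_covers(conds, X, cols) & unassigned
        p = int((y[m] == target).sum())
        n = int(m.sum()) - p
        out.append(Rule(tuple(conds), target, coverage=(p, n)))
        unassigned &= ~m
    p_def = int((y[unassigned] == default).sum())
    n_def = int(unassigned.sum()) - p_def
    return RuleSet(tuple(out), default, default_coverage=(p_def, n_def))


def ripper_factory(cfg: RipperConfig = RipperConfig()):
    """Classifier factory for the cross-validation harness."""

    def fit(table: FeatureTable, seed: int) -> Predictor:
        rs = ripper_fit(table, replace(cfg, seed=seed))
        return ruleset_predictor(rs, table.feature_names)

    return fit
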