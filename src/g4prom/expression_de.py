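"""Expression-side selection of differentially expressed genes.

The selection mirrors a classic microarray workflow: quantile
normalization of the probe x sample intensity matrix, a per-probe one-way
fixed-effects ANOVA across conditions, a Pearson correlation of each probe
against a 0/1 condition-of-interest indicator, and thresholding
(ANOVA p <= 0.05 and r >= 0.9 by default). Probes with ANOVA p > 0.75 form
the "unchanged" reference set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from g4prom.sequence_io import GeneList

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with sample -> condition labels."""

    values: pd.DataFrame  # index = probe_ids, columns = sample_ids
    groups: dict[str, str]  # sample_id -> condition label

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise ValueError("expression matrix contains non-numeric columns")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)[:10]}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.groups[s], None)
        return list(seen)


@dataclass
class DESelection:
    """Result of thresholded selection: probe statistics and gene sets."""

    anova_p: pd.Series
    r_up: pd.Series
    r_down: pd.Series
    p_max: float
    r_min: float
    p_unchanged: float
    up: GeneList = field(default=None)  # type: ignore[assignment]
    down: GeneList = field(default=None)  # type: ignore[assignment]
    unchanged: GeneList = field(default=None)  # type: ignore[assignment]
    up_probes: frozenset[str] = frozenset()
    down_probes: frozenset[str] = frozenset()
    unchanged_probes: frozenset[str] = frozenset()


def read_expression_matrix(matrix_path, samples_path) -> ExpressionMatrix:
    """Read a TSV matrix (first column probe_id) and a sample sheet TSV
    with columns sample_id, condition."""
    values = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "condition"} <= set(sheet.columns):
        raise ValueError("sample sheet must have columns sample_id, condition")
    groups = dict(zip(sheet["sample_id"], sheet["condition"]))
    return ExpressionMatrix(values, groups)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic quantile normalization.

    Every column is replaced by the mean of all columns' order statistics
    at its ranks; ties within a column receive the mean of the candidate
    values (average ranks interpolate between adjacent order-statistic
    means). Afterwards all columns share one empirical distribution.
    """
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[0]
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks - 1.0, np.arange(n), ref)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), dict(m.groups)
    )


def anova_per_probe(m: ExpressionMatrix) -> pd.Series:
    """One-way fixed-effects ANOVA F-test per probe, p from F(g-1, n-g).

    Probes where both the within- and between-group sums of squares vanish
    (a constant probe) get p = 1 by convention; the count is logged.
    """
    conditions = m.conditions
    if len(conditions) < 2:
        raise ValueError("ANOVA needs >= 2 conditions")
    cols_by_group = {
        c: [s for s in m.sample_ids if m.groups[s] == c] for c in conditions
    }
    sizes = np.array([len(cols_by_group[c]) for c in conditions])
    if (sizes < 2).any():
        raise ValueError("each condition needs >= 2 replicates for ANOVA")
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[1]
    g = len(conditions)
    grand = vals.mean(axis=1)
    ssb = np.zeros(vals.shape[0])
    ssw = np.zeros(vals.shape[0])
    col_index = {s: i for i, s in enumerate(m.sample_ids)}
    for c in conditions:
        idx = [col_index[s] for s in cols_by_group[c]]
        sub = vals[:, idx]
        gm = sub.mean(axis=1)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((sub - gm[:, None]) ** 2).sum(axis=1)
    dfb, dfw = g - 1, n - g
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    degenerate = (ssw == 0) & (ssb == 0)
    if degenerate.any():
        logger.info("anova_per_probe: %d constant probes set to p = 1", int(degenerate.sum()))
        p[degenerate] = 1.0
    # zero within-group variance with real between-group signal: F = inf, p = 0
    p[np.isnan(p) & ~degenerate] = 0.0
    return pd.Series(p, index=m.values.index, name="anova_p")


def profile_correlation(m: ExpressionMatrix, condition: str) -> pd.Series:
    """Pearson correlation of each probe against the 0/1 indicator of
    ``condition`` over samples.

    Zero-variance probes get NaN (excluded from selection downstream); the
    excluded count is logged. Correlation against the negated indicator is
    simply the negative of this value.
    """
    if condition not in m.conditions:
        raise ValueError(f"condition {condition!r} not in sample groups {m.conditions}")
    indicator = np.array([1.0 if m.groups[s] == condition else 0.0 for s in m.sample_ids])
    if indicator.std() == 0:
        raise ValueError("condition indicator has zero variance (all samples one group)")
    vals = m.values.to_numpy(dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    ic = indicator - indicator.mean()
    denom = np.sqrt((vc**2).sum(axis=1) * (ic**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vc @ ic) / denom
    n_excluded = int(np.isnan(r).sum())
    if n_excluded:
        logger.info("profile_correlation: %d zero-variance probes excluded", n_excluded)
    return pd.Series(r, index=m.values.index, name=f"r_{condition}")


def select_sets(
    anova_p: pd.Series,
    r_up: pd.Series,
    r_down: pd.Series,
    probe_to_gene: pd.DataFrame | None = None,
    p_max: float = 0.05,
    r_min: float = 0.9,
    p_unchanged: float = 0.75,
    set_name: str = "selection",
) -> DESelection:
    """Threshold probe statistics into up/down/unchanged gene sets.

    up: p <= p_max and r_up >= r_min; down: p <= p_max and r_down >= r_min;
    unchanged: p > p_unchanged. ``probe_to_gene`` maps probe_id -> gene_id
    (many-to-many allowed, genes deduplicated); by default probes are their
    own genes. With r_min > 0 a probe can never be both up and down.
    """
    if not (anova_p.index.equals(r_up.index) and anova_p.index.equals(r_down.index)):
        raise ValueError("statistic vectors are not aligned on the same probes")
    usable = ~(r_up.isna() | r_down.isna())
    up_mask = usable & (anova_p <= p_max) & (r_up >= r_min)
    down_mask = usable & (anova_p <= p_max) & (r_down >= r_min)
    assert not (up_mask & down_mask).any(), "a probe selected both up and down"
    unchanged_mask = anova_p > p_unchanged

    def to_genes(mask: pd.Series) -> frozenset[str]:
        probes = set(anova_p.index[mask])
        if probe_to_gene is None:
            return frozenset(probes)
        sub = probe_to_gene[probe_to_gene["probe_id"].isin(probes)]
        return frozenset(sub["gene_id"])

    up_genes = to_genes(up_mask)
    down_genes = to_genes(down_mask)
    unchanged_genes = to_genes(unchanged_mask) - up_genes - down_genes
    return DESelection(
        anova_p=anova_p,
        r_up=r_up,
        r_down=r_down,
        p_max=p_max,
        r_min=r_min,
        p_unchanged=p_unchanged,
        up=GeneList(set_name, "up", up_genes),
        down=GeneList(set_name, "down", down_genes),
        unchanged=GeneList(set_name, "unchanged", unchanged_genes),
        up_probes=frozenset(anova_p.index[up_mask]),
        down_probes=frozenset(anova_p.index[down_mask]),
        unchanged_probes=frozenset(anova_p.index[unchanged_mask]),
    )


def intersect_selections(selections: list[DESelection], set_name: str = "intersection") -> dict[str, GeneList]:
    """Gene-wise intersection of several selections, per direction.

    Used to require a change against every control contrast (e.g. untreated
    and an inactive control compound) before calling a gene differential.
    """
    if not selections:
        raise ValueError("need at least one selection")
    out = {}
    for direction in ("up", "down", "unchanged"):
        genes = getattr(selections[0], direction).gene_ids
        for sel in selections[1:]:
            genes = genes & getattr(sel, direction).gene_ids
        out[direction] = GeneList(set_name, direction, genes)
    return out


def benjamini_hochberg(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values, emitted alongside raw p for
    users; raw p drives the selection."""
    q = stats.false_discovery_control(p.to_numpy(), method="bh")
    return pd.Series(q, index=p.index, name="q")
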