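"""Solubility-fraction proteomics: normalization, detection filtering,
age fold-changes, solubility shifts, eigengenes, and correlation networks.

Samples come from a sequential-extraction workflow that splits each tissue
piece into cytoplasmic, nuclear, membrane, and cytoskeletal fractions plus a
final insoluble pellet, ordering proteins by decreasing solubility.  All
statistics operate on an :class:`IntensityTable` — a protein × sample matrix
with per-sample metadata (mouse, age group, region, fraction, cognitive
status) and a per-protein class annotation (matrisome / synapse /
innate-immune / microglia-enriched / other).

Missing intensities stay missing everywhere except the per-mouse total
intensity, where an absent fraction contributes zero physical signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

import networkx as nx
import statsmodels.api as sm

#: Fractions ordered from most to least soluble.
FRACTION_ORDER = ("cytoplasmic", "nuclear", "membrane", "cytoskeletal", "insoluble")

SAMPLE_COLUMNS = ("mouse", "age_group", "sex", "region", "fraction", "cognitive_status")


@dataclass
class IntensityTable:
    """Protein × sample intensity matrix with metadata.

    ``values``: DataFrame indexed by protein, one column per sample id,
    NaN for missing.  ``samples``: DataFrame indexed by sample id with the
    metadata columns.  ``proteins``: DataFrame indexed by protein with at
    least a ``protein_class`` column.  ``log2`` flags the intensity scale.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame
    log2: bool = False

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns and sample metadata disagree")
        if not self.log2 and (self.values < 0).any().any():
            raise ValueError("raw intensities must be non-negative")

    def linear(self) -> pd.DataFrame:
        return np.power(2.0, self.values) if self.log2 else self.values

    def to_log2(self) -> "IntensityTable":
        if self.log2:
            return self
        vals = self.values.where(self.values > 0)  # zeros are non-detections
        return replace(self, values=np.log2(vals), log2=True)


def filter_samples(table: IntensityTable, **criteria) -> IntensityTable:
    """Subset a table to samples matching metadata criteria.

    Example: ``filter_samples(table, fraction="membrane")`` — age
    fold-change tests are run per fraction, each examined independently.
    """
    keep = pd.Series(True, index=table.samples.index)
    for col, val in criteria.items():
        keep &= table.samples[col] == val
    ids = list(keep.index[keep])
    return replace(table, values=table.values[ids], samples=table.samples.loc[ids])


def _quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across columns; NaNs are excluded and preserved.

    Each sample's observed values are mapped, by rank, onto the rank-wise
    mean of the samples' sorted values; samples with fewer observations are
    matched through interpolated quantiles.
    """
    counts = mat.notna().sum(axis=0)
    if (counts == 0).any():
        empty = list(counts.index[counts == 0])
        raise ValueError(f"sample(s) with zero observed values: {empty}")
    L = int(counts.max())
    grid = (np.arange(L) + 0.5) / L
    ref = np.zeros(L)
    for s in mat.columns:
        v = np.sort(mat[s].dropna().to_numpy())
        if len(v) == L:
            ref += v
        else:
            q = (np.arange(len(v)) + 0.5) / len(v)
            ref += np.interp(grid, q, v)
    ref /= mat.shape[1]

    out = mat.copy()
    for s in mat.columns:
        obs = mat[s].dropna()
        n = len(obs)
        q = (np.arange(n) + 0.5) / n
        new = ref if n == L else np.interp(q, grid, ref)
        ranked = np.empty(n)
        ranked[np.argsort(obs.to_numpy(), kind="stable")] = new
        out.loc[obs.index, s] = ranked
    return out


def normalize(table: IntensityTable, per_fraction: bool = True) -> IntensityTable:
    """Batch correction: quantile normalization then per-sample median centering.

    Intensities are log2-transformed if still on the linear scale.  By
    default samples are quantile-normalized within each solubility fraction
    (fractions have genuinely different global distributions); set
    ``per_fraction=False`` for one global normalization.
    """
    if table.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    t = table.to_log2()
    vals = t.values.copy()
    if per_fraction:
        for _, ids in t.samples.groupby("fraction", sort=False).groups.items():
            vals[list(ids)] = _quantile_normalize(vals[list(ids)])
    else:
        vals = _quantile_normalize(vals)
    vals = vals - vals.median(axis=0, skipna=True)
    return replace(t, values=vals)


def detection_filter(
    table: IntensityTable, min_frac: float = 0.75, grouping: str = "region"
) -> IntensityTable:
    """Keep proteins detected in at least ``min_frac`` of samples per group.

    A protein is retained if, within every grouping unit (brain region by
    default), it is observed in >= ``min_frac`` of that unit's samples.
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must lie in (0, 1]")
    keep = pd.Series(True, index=table.values.index)
    for _, ids in table.samples.groupby(grouping, sort=False).groups.items():
        frac = table.values[list(ids)].notna().mean(axis=1)
        keep &= frac >= min_frac
    return replace(
        table,
        values=table.values.loc[keep],
        proteins=table.proteins.loc[keep.index[keep].intersection(table.proteins.index)],
    )


def total_intensity(table: IntensityTable) -> IntensityTable:
    """Per-mouse intensity summed over solubility fractions, log2-normalized.

    Linear-scale signal is summed across fractions (a fraction in which the
    protein was not observed contributes zero); a protein missing in every
    fraction for a mouse yields a missing total.  The result holds one
    sample per (mouse, region).
    """
    lin = table.linear()
    groups = table.samples.groupby(["mouse", "region"], sort=False, dropna=False)
    cols, meta_rows = {}, []
    for (mouse, region), sub in groups:
        ids = list(sub.index)
        block = lin[ids]
        any_obs = block.notna().any(axis=1)
        total = block.fillna(0.0).sum(axis=1).where(any_obs)
        sid = f"{mouse}__{region}"
        cols[sid] = np.log2(total)
        row = {c: sub.iloc[0].get(c) for c in SAMPLE_COLUMNS}
        row["fraction"] = "total"
        meta_rows.append(pd.Series(row, name=sid))
    values = pd.DataFrame(cols)
    samples = pd.DataFrame(meta_rows)
    return IntensityTable(values, samples, table.proteins, log2=True)


def fold_change_test(
    table: IntensityTable,
    group_var: str = "age_group",
    numerator: str = "aged",
    denominator: str = "young",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-protein aged/young fold change with a two-sided unpaired t-test.

    The fold change is the ratio of linear-scale group means
    (numerator / denominator); the Student (equal-variance) t-test runs on
    log2 intensities.  Proteins with fewer than 2 observations in either
    group are flagged missing (NaN).  ``bh_correct`` adds a
    Benjamini-Hochberg adjusted column.
    """
    t = table.to_log2()
    ids_num = list(t.samples.index[t.samples[group_var] == numerator])
    ids_den = list(t.samples.index[t.samples[group_var] == denominator])
    if not ids_num or not ids_den:
        raise ValueError(f"group_var {group_var!r} lacks {numerator!r}/{denominator!r} samples")
    log_num, log_den = t.values[ids_num], t.values[ids_den]
    lin_num, lin_den = np.power(2.0, log_num), np.power(2.0, log_den)

    n_num = log_num.notna().sum(axis=1)
    n_den = log_den.notna().sum(axis=1)
    ok = (n_num >= 2) & (n_den >= 2)
    fc = lin_num.mean(axis=1, skipna=True) / lin_den.mean(axis=1, skipna=True)
    res = stats.ttest_ind(log_num, log_den, axis=1, equal_var=True, nan_policy="omit")
    pvals = pd.Series(np.asarray(res.pvalue), index=t.values.index)
    # degenerate zero-variance proteins: identical groups are p = 1, a pure
    # offset with no scatter is p = 0
    degen = pvals.isna() & ok
    if degen.any():
        equal = (log_num.mean(axis=1) - log_den.mean(axis=1)).abs() < 1e-12
        pvals[degen] = np.where(equal[degen], 1.0, 0.0)
    out = pd.DataFrame(
        {
            "fold_change": fc.where(ok),
            "log2_fold_change": np.log2(fc).where(ok),
            "p_value": pvals.where(ok),
            "n_" + numerator: n_num,
            "n_" + denominator: n_den,
        }
    )
    out.attrs["test"] = "unpaired two-sided Student t (equal variance) on log2 intensities"
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        mask = out["p_value"].notna()
        adj = pd.Series(np.nan, index=out.index)
        if mask.any():
            adj[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adj_bh"] = adj
    return out


def solubility_shift(table: IntensityTable, alpha: float = 0.05) -> pd.DataFrame:
    """Age-related solubility shifts for proteins seen in >= 2 fractions.

    For each eligible protein the most-soluble and most-insoluble detected
    fractions (by the sequential-extraction order) form a pair; every mouse
    observed in both contributes a log2 difference (soluble − insoluble,
    i.e. the fold change relative to the more insoluble fraction).  Young
    and aged differences are compared with a two-sided unpaired t-test:
    ``more_soluble`` if the aged difference exceeds the young at p < alpha,
    ``more_insoluble`` if reversed, otherwise ``none``.
    """
    t = table.to_log2()
    meta = t.samples
    rows = []
    for protein, vals in t.values.iterrows():
        obs = vals.dropna()
        fr_present = [f for f in FRACTION_ORDER if f in set(meta.loc[obs.index, "fraction"])]
        if len(fr_present) < 2:
            continue
        f_sol, f_insol = fr_present[0], fr_present[-1]
        diffs: dict[str, list[float]] = {"young": [], "aged": []}
        for (mouse, age), sub in meta.loc[obs.index].groupby(["mouse", "age_group"], sort=False):
            by_fraction = {meta.loc[s, "fraction"]: obs[s] for s in sub.index}
            if f_sol in by_fraction and f_insol in by_fraction and age in diffs:
                diffs[age].append(by_fraction[f_sol] - by_fraction[f_insol])
        if len(diffs["young"]) < 2 or len(diffs["aged"]) < 2:
            continue
        t_res = stats.ttest_ind(diffs["aged"], diffs["young"], equal_var=True)
        delta = float(np.mean(diffs["aged"]) - np.mean(diffs["young"]))
        direction = "none"
        if t_res.pvalue < alpha:
            direction = "more_soluble" if delta > 0 else "more_insoluble"
        rows.append(
            {
                "protein": protein,
                "fraction_soluble": f_sol,
                "fraction_insoluble": f_insol,
                "young_log2fc": float(np.mean(diffs["young"])),
                "aged_log2fc": float(np.mean(diffs["aged"])),
                "p_value": float(t_res.pvalue),
                "direction": direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "fraction_soluble",
            "fraction_insoluble",
            "young_log2fc",
            "aged_log2fc",
            "p_value",
            "direction",
        ],
    ).set_index("protein") if rows else pd.DataFrame(
        columns=[
            "fraction_soluble",
            "fraction_insoluble",
            "young_log2fc",
            "aged_log2fc",
            "p_value",
            "direction",
        ]
    )


def module_eigengene(table: IntensityTable, module_members: "set[str] | list[str]") -> pd.Series:
    """First principal component of a module's standardized member profiles.

    Missing member intensities are imputed with the per-protein mean before
    standardization.  The sign is fixed so the eigengene correlates
    positively with the members' mean profile.
    """
    members = [m for m in module_members if m in table.values.index]
    if len(members) < 2:
        raise ValueError("need at least 2 module members present in the table")
    if table.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = table.to_log2().values.loc[members].copy()
    x = x.apply(lambda row: row.fillna(row.mean()), axis=1)
    mat = x.to_numpy(float)
    sd = mat.std(axis=1, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    mat = (mat - mat.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    score = vt[0]
    mean_profile = mat.mean(axis=0)
    if np.dot(score, mean_profile) < 0:
        score = -score
    return pd.Series(score, index=table.values.columns, name="eigengene")


def trait_correlation(values: np.ndarray, trait: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation of a per-sample measure with a (possibly binary) trait.

    Binary traits coded 0/1 give the point-biserial correlation; the p-value
    comes from the two-sided t distribution on n − 2 degrees of freedom.
    Returns ``(r, r², p)``.
    """
    values = np.asarray(values, float)
    trait = np.asarray(trait, float)
    if len(values) != len(trait) or len(values) < 3:
        raise ValueError("need >= 3 paired samples")
    if np.std(values) == 0 or np.std(trait) == 0:
        raise ValueError("zero variance in values or trait")
    r, p = stats.pearsonr(values, trait)
    return float(r), float(r * r), float(p)


def robust_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Bisquare (Tukey biweight, c = 4.685) IRLS regression of y on x.

    Returns ``(slope, intercept, p)`` with a two-sided test on the slope;
    gross outliers are down-weighted to zero influence.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 points")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.pvalues[1])


def correlation_network(measures: pd.DataFrame, min_pairs: int = 3) -> nx.Graph:
    """Pairwise-Pearson correlation network over a variable × subject matrix.

    Correlations use pairwise deletion of missing data; self-correlations on
    the diagonal are set to zero so the graph has no self-links.  Edge
    weights are the signed r values.  A variable with fewer than
    ``min_pairs`` paired observations against every other variable is an
    error.
    """
    if measures.shape[0] < 2:
        raise ValueError("need at least 2 variables")
    corr = measures.T.corr(method="pearson", min_periods=min_pairs)
    pair_counts = (measures.notna().astype(int) @ measures.notna().astype(int).T).to_numpy()
    np.fill_diagonal(pair_counts, 0)
    isolated = [v for i, v in enumerate(measures.index) if pair_counts[i].max() < min_pairs]
    if isolated:
        raise ValueError(f"variable(s) with < {min_pairs} paired observations: {isolated}")
    mat = corr.to_numpy()
    np.fill_diagonal(mat, 0.0)
    g = nx.Graph()
    g.add_nodes_from(measures.index)
    for i, a in enumerate(measures.index):
        for j in range(i + 1, len(measures.index)):
            if np.isfinite(mat[i, j]):
                g.add_edge(a, measures.index[j], weight=float(mat[i, j]))
    return g
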