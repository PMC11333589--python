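"""Configuration-comparison statistics for the breast-density protocol.

The protocol probes each breast in several configurations (sitting vs supine,
reflectance at rho = 2 or 3 cm vs compressed transmittance, outer / lower /
inner quadrants).  This module reproduces the study's statistical machinery
on the resulting parameter tables:

* Pearson correlation (with exact t-based p) between transmittance -- the
  reference configuration validated against mammography in earlier work --
  and each reflectance configuration, for seven tissue parameters;
* Wilcoxon matched-pairs signed-rank tests for paired configuration
  differences (exact two-sided p by full sign enumeration for n <= 25,
  midranks for ties; normal approximation with tie correction above);
* Bonferroni multiplicity adjustment (raw p always retained alongside);
* a subject density ranking keyed on the Optical Index in a reference
  configuration, with per-column rank concordance (Spearman by default),
  lipid entered with inverted polarity since it anti-correlates with
  density.

Parameter tables are plain pandas DataFrames with one row per fitted
acquisition; see :data:`METADATA_COLUMNS` and :data:`PARAMETER_COLUMNS`.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

METADATA_COLUMNS = ["subject_id", "breast", "posture", "position", "distance_cm", "mode"]
PARAMETER_COLUMNS = ["tHb", "SO2", "lipids", "water", "collagen", "a", "b", "OI", "CI"]
#: the seven parameters of the transmittance-vs-reflectance correlation report
CORRELATION_PARAMETERS = ["tHb", "SO2", "lipids", "water", "collagen", "a", "b"]
#: the parameters shown in the density-ranking display
RANKING_PARAMETERS = ["water", "lipids", "collagen", "b", "OI", "CI"]

#: reference configuration of the density ranking: supine subject, right
#: breast, outer quadrants, rho = 3 cm
DEFAULT_RANKING_REFERENCE: Mapping[str, object] = {
    "posture": "supine",
    "breast": "R",
    "position": "O",
    "distance_cm": 3.0,
    "mode": "reflectance",
}


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the exact t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    """(W+, midranks of |d|) on the nonzero differences."""
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumeration of all 2^n sign assignments.

    Computed through the distribution of the positive-rank sum (a subset-sum
    convolution over the doubled midranks -- identical to brute-force
    enumeration, channel for channel).  Two-sided p is
    2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    r2 = np.rint(2.0 * ranks).astype(int)  # doubled midranks are integers
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    total = dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = dist[: w2 + 1].sum() / total
    p_ge = dist[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped; |differences| are midranked (ties allowed).
    Returns (W+, p) with p exact (full sign enumeration) for n <= exact_max_n
    and from the tie-corrected normal approximation (no continuity
    correction) above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero: test undefined")
    w_plus, ranks = _signed_rank_statistic(d)
    if n <= exact_max_n:
        return w_plus, _exact_signed_rank_p(w_plus, ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - mean) / np.sqrt(var)
    return w_plus, float(2.0 * sps.norm.sf(abs(z)))


def bonferroni_adjust(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m * p), family size m (default len)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size must be >= 1")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# parameter-table machinery
# ---------------------------------------------------------------------------


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"parameter table is missing metadata columns: {missing}")


def breast_averaged(table: pd.DataFrame, parameters: Iterable[str] | None = None) -> pd.DataFrame:
    """Average parameter values over left and right breasts.

    Subject-level tests are run on breast-averaged values (as in the study's
    figure captions); pass the raw table instead for left-vs-right analyses.
    """
    _validate_table(table)
    params = list(parameters) if parameters is not None else [
        c for c in PARAMETER_COLUMNS if c in table.columns
    ]
    keys = ["subject_id", "posture", "position", "mode", "distance_cm"]
    return (
        table.groupby(keys, dropna=False, as_index=False)[params].mean(numeric_only=True)
    )


def _config_subject_means(
    table: pd.DataFrame, posture: str, distance_cm: float | None, mode: str,
    parameters: Sequence[str],
) -> pd.DataFrame:
    """Per-subject means (over breasts and probing positions) for one
    (posture, distance, mode) configuration group."""
    sel = (table["posture"] == posture) & (table["mode"] == mode)
    if distance_cm is not None:
        sel &= table["distance_cm"] == distance_cm
    sub = table.loc[sel]
    if sub.empty:
        raise ValueError(f"no rows for configuration ({posture}, {distance_cm}, {mode})")
    return sub.groupby("subject_id", as_index=True)[list(parameters)].mean(numeric_only=True)


def configuration_correlations(
    table: pd.DataFrame,
    parameters: Sequence[str] = tuple(CORRELATION_PARAMETERS),
    family_size: int | None = None,
) -> pd.DataFrame:
    """Transmittance-vs-reflectance correlation report (Table-2 layout).

    For each of the seven tissue parameters and each of the four reflectance
    configurations (sitting/supine x rho = 2/3 cm), Pearson r between the
    per-subject transmittance value and the per-subject reflectance value
    (both averaged over breasts, and over probing positions within the
    configuration), with raw and Bonferroni-adjusted p.  The default family
    is every cell of the report (len(parameters) * 4 = 28).
    """
    _validate_table(table)
    trans = _config_subject_means(table, "sitting", None, "transmittance", parameters)
    configs = [
        ("sitting", 2.0),
        ("sitting", 3.0),
        ("supine", 2.0),
        ("supine", 3.0),
    ]
    rows = []
    for posture, dist in configs:
        refl = _config_subject_means(table, posture, dist, "reflectance", parameters)
        joined = trans.join(refl, lsuffix="_t", rsuffix="_r", how="inner")
        if len(joined) < 3:
            raise ValueError("need at least 3 subjects common to both configurations")
        for param in parameters:
            r, p = pearson_with_p(joined[f"{param}_t"], joined[f"{param}_r"])
            rows.append(
                {
                    "parameter": param,
                    "posture": posture,
                    "distance_cm": dist,
                    "r": r,
                    "p_raw": p,
                    "n": len(joined),
                }
            )
    report = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(report)
    report["p_adj"] = bonferroni_adjust(report["p_raw"].to_numpy(), m)
    report["m_family"] = m
    return report


def paired_config_comparison(
    table: pd.DataFrame,
    config_a: Mapping[str, object],
    config_b: Mapping[str, object],
    parameter: str,
    family_size: int = 1,
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test of one parameter between two configurations.

    Configurations are metadata selectors, e.g.
    ``{"posture": "supine", "position": "O", "distance_cm": 3.0}``.  Values
    are breast-averaged per subject first; subjects present in only one
    configuration are dropped with a warning.  Returns
    (W+, raw p, Bonferroni-adjusted p).
    """
    _validate_table(table)
    avg = breast_averaged(table, [parameter])

    def subject_series(cfg: Mapping[str, object]) -> pd.Series:
        sel = np.ones(len(avg), dtype=bool)
        for key, val in cfg.items():
            sel &= (avg[key] == val).to_numpy()
        sub = avg.loc[sel]
        if sub.empty:
            raise ValueError(f"no rows match configuration {dict(cfg)}")
        return sub.groupby("subject_id")[parameter].mean()

    a = subject_series(config_a)
    b = subject_series(config_b)
    common = a.index.intersection(b.index)
    if len(common) < len(a) or len(common) < len(b):
        warnings.warn(
            f"dropping {len(a) + len(b) - 2 * len(common)} unpaired subject entries",
            stacklevel=2,
        )
    if len(common) == 0:
        raise ValueError("no subjects are paired across the two configurations")
    stat, p = wilcoxon_signed_rank(a.loc[common].to_numpy(), b.loc[common].to_numpy())
    p_adj = float(bonferroni_adjust([p], family_size)[0])
    return stat, p, p_adj


def density_ranking(
    table: pd.DataFrame,
    reference: Mapping[str, object] | None = None,
    parameters: Sequence[str] = tuple(RANKING_PARAMETERS),
    method: str = "spearman",
) -> dict:
    """Subject density ranking keyed on OI in a reference configuration.

    Subjects are ordered by ascending Optical Index in the reference
    configuration (default: supine, right breast, outer quadrants, 3 cm).
    For every (parameter, configuration) column the per-subject values are
    rank-correlated against the reference ordering (Spearman by default,
    Kendall available); the lipid column is negated first, since lipid
    content anti-correlates with breast density.

    Returns ``{"order": [subject ids, ascending OI], "reference": <dict>,
    "concordance": DataFrame}`` with one concordance row per
    (parameter, breast, posture, position, distance_cm, mode) column.
    """
    _validate_table(table)
    if method not in ("spearman", "kendall"):
        raise ValueError("method must be 'spearman' or 'kendall'")
    corr = sps.spearmanr if method == "spearman" else sps.kendalltau
    reference = dict(DEFAULT_RANKING_REFERENCE if reference is None else reference)

    sel = np.ones(len(table), dtype=bool)
    for key, val in reference.items():
        sel &= (table[key] == val).to_numpy()
    ref_rows = table.loc[sel]
    if ref_rows.empty:
        raise ValueError(f"no rows match the reference configuration {reference}")
    ref_oi = ref_rows.set_index("subject_id")["OI"]
    subjects = set(table["subject_id"])
    if set(ref_oi.index) != subjects:
        raise ValueError("reference configuration missing for some subjects")
    order = ref_oi.sort_values().index.tolist()
    ref_rank = ref_oi.rank()

    config_keys = ["breast", "posture", "position", "distance_cm", "mode"]
    rows = []
    for cfg_vals, group in table.groupby(config_keys, dropna=False):
        values = group.set_index("subject_id")
        common = ref_rank.index.intersection(values.index)
        for param in parameters:
            col = values.loc[common, param]
            signed = -col if param == "lipids" else col
            rho = corr(ref_rank.loc[common].to_numpy(), signed.to_numpy()).statistic
            rows.append(
                dict(zip(config_keys, cfg_vals))
                | {"parameter": param, "concordance": float(rho), "n": len(common)}
            )
    return {"order": order, "reference": reference, "concordance": pd.DataFrame(rows)}
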