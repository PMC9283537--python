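"""Integrative urine/tissue statistics.

Creatinine normalization (and the stoichiometry it supports), differential
metabolite filtering (Welch or paired t-test with fold-change and BH-q
thresholds), and cross-compartment correlation edge sets between matched
tissue and fluid matrices from the same animals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "creatinine_normalize",
    "differential_metabolites",
    "cross_compartment_correlations",
    "aggregate_edges_by_class",
]


def creatinine_normalize(values: pd.Series | pd.DataFrame,
                         creatinine: pd.Series):
    """Divide per-sample analyte values by per-sample creatinine.

    Homogeneous of degree 1 in the analyte and -1 in creatinine, which is
    what makes it invariant to diuresis (urine volume cancels).
    """
    cr = creatinine.reindex(
        values.index if isinstance(values, pd.Series) else values.columns
    )
    bad = cr[(cr.isna()) | (cr <= 0)]
    if len(bad):
        raise ValueError(
            f"creatinine must be > 0 for every sample; offending: "
            f"{list(bad.index)}"
        )
    if isinstance(values, pd.Series):
        return values / cr
    return values.div(cr, axis=1)


def differential_metabolites(
    matrix: pd.DataFrame,
    groups: pd.Series,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    q_max: float = 0.05,
    paired: bool = False,
    group_order: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-metabolite two-group test with FC / p / BH-q filtering.

    ``matrix`` is metabolites x samples; ``groups`` maps sample -> label
    (exactly two labels). Unpaired uses Welch's t-test on log10 values;
    ``paired=True`` uses a paired two-tailed t-test over samples matched
    by column order within group. The BH family is all metabolites in the
    matrix. A metabolite passes iff |FC| direction-agnostic fold change
    >= fc_min, p < p_max and q < q_max.
    """
    groups = groups.reindex(matrix.columns)
    if groups.isna().any():
        raise ValueError(
            f"group labels missing for samples: "
            f"{list(matrix.columns[groups.isna()])}"
        )
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if group_order is not None:
        labels = list(group_order)
    a_cols = matrix.columns[groups == labels[0]]
    b_cols = matrix.columns[groups == labels[1]]
    if paired and len(a_cols) != len(b_cols):
        raise ValueError("paired test requires complete pairs")
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >=2 samples per group")

    floor = 1.0
    a = np.maximum(matrix[a_cols].to_numpy(float), floor)
    b = np.maximum(matrix[b_cols].to_numpy(float), floor)
    fc = a.mean(axis=1) / b.mean(axis=1)
    log_a, log_b = np.log10(a), np.log10(b)
    # degenerate (zero-variance) rows are resolved explicitly below; keep
    # scipy quiet about them
    import warnings
    if paired:
        diffs = log_a - log_b
        sd = diffs.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_rel(log_a, log_b, axis=1)
        p = np.where(sd == 0,
                     np.where(diffs.mean(axis=1) == 0, 1.0, 0.0),
                     res.pvalue)
    else:
        with np.errstate(invalid="ignore", divide="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        degenerate = (log_a.std(axis=1) == 0) & (log_b.std(axis=1) == 0)
        p = np.where(degenerate,
                     np.where(log_a.mean(axis=1) == log_b.mean(axis=1),
                              1.0, 0.0),
                     res.pvalue)
    p = np.nan_to_num(p, nan=1.0)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    effect_fc = np.maximum(fc, 1.0 / fc)   # direction-agnostic magnitude
    out = pd.DataFrame({
        "metabolite": matrix.index,
        "fold_change": fc,
        "log2_fc": np.log2(fc),
        "p_value": p,
        "q_value": q,
        "passes": (effect_fc >= fc_min) & (p < p_max) & (q < q_max),
    }).set_index("metabolite")
    return out


def cross_compartment_correlations(
    tissue: pd.DataFrame,
    fluid: pd.DataFrame,
    animal_map: dict[str, str] | None = None,
    q_max: float = 0.05,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Correlate every tissue x fluid metabolite pair across animals.

    Matrices are metabolites x animals (columns are animal ids, or sample
    ids translated through ``animal_map``; replicates of one animal are
    averaged). Correlations are Pearson on log10 values by default
    (Spearman switchable); BH correction runs over all pairs and retained
    edges satisfy q <= q_max, partitioned by sign.
    """
    def to_animals(m: pd.DataFrame) -> pd.DataFrame:
        if animal_map:
            m = m.rename(columns=animal_map)
            m = m.T.groupby(level=0).mean().T
        return m

    t, f = to_animals(tissue), to_animals(fluid)
    shared = [a for a in t.columns if a in f.columns]
    if len(shared) < 4:
        raise ValueError(
            f"need >=4 linked animals for correlation, got {len(shared)}"
        )
    t, f = t[shared], f[shared]
    if log_transform:
        t = np.log10(np.maximum(t, 1e-12))
        f = np.log10(np.maximum(f, 1e-12))
    rows = []
    for mt in t.index:
        x = t.loc[mt].to_numpy(float)
        for mf in f.index:
            y = f.loc[mf].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                r, p = 0.0, 1.0
            elif method == "pearson":
                r, p = stats.pearsonr(x, y)
            elif method == "spearman":
                r, p = stats.spearmanr(x, y)
            else:
                raise ValueError(f"unknown correlation method {method!r}")
            rows.append({"tissue_metabolite": mt, "fluid_metabolite": mf,
                         "r": float(r), "p_value": float(p)})
    edges = pd.DataFrame(rows)
    _, q, _, _ = multipletests(edges["p_value"], method="fdr_bh")
    edges["q_value"] = q
    edges["sign"] = np.sign(edges["r"]).astype(int)
    edges["retained"] = edges["q_value"] <= q_max
    return edges


def aggregate_edges_by_class(
    edges: pd.DataFrame,
    tissue_classes: dict[str, str],
    fluid_classes: dict[str, str],
) -> pd.DataFrame:
    """Count retained edges per (tissue class, fluid class, sign).

    This is the long-format statistic behind chord-diagram rendering.
    """
    kept = edges[edges["retained"]].copy()
    if kept.empty:
        return pd.DataFrame(columns=["tissue_class", "fluid_class", "sign",
                                     "n_edges"])
    kept["tissue_class"] = kept["tissue_metabolite"].map(tissue_classes)
    kept["fluid_class"] = kept["fluid_metabolite"].map(fluid_classes)
    return (
        kept.groupby(["tissue_class", "fluid_class", "sign"])
        .size().rename("n_edges").reset_index()
    )
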