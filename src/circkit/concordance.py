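"""MET-status classification, cross-assay concordance, and longitudinal tracking.

Tumor samples are classified High/Low MET primarily from phospho-MET IHC
(a functionally active receptor); where that is missing the call falls back
to strong gene-copy-number amplification by FISH. Pairwise concordance
between detection methods (IHC, FISH, tissue and plasma circRNA assays) is
computed either with the literal both-or-either formula — the number of
samples positive (or negative) by both methods over the sum of samples
positive (or negative) by either or both, which double-counts discordant
samples in the denominator — or as simple agreement. Longitudinal plasma
series are scanned for the emergence of a resistance marker above a fold
threshold over a pre-treatment baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "MetStatus",
    "read_call_table",
    "read_longitudinal",
    "classify_met_status",
    "binarize_continuous",
    "pairwise_concordance",
    "concordance_matrix",
    "plot_concordance_heatmap",
    "track_emergence",
]

METHODS = (
    "IHC_MET",
    "IHC_pMET",
    "FISH_GCN",
    "FISH_ratio",
    "tissue_circMET",
    "plasma_circMET",
)
CALLS = ("positive", "negative", "missing")


@dataclass
class MetStatus:
    sample_id: str
    status: str  # High | Low | unclassifiable
    basis: str | None  # pMET_IHC | FISH_amplification | None


def read_call_table(path) -> pd.DataFrame:
    """Read an assay-call CSV (sample_id, method, call[, value])."""
    df = pd.read_csv(path)
    required = {"sample_id", "method", "call"}
    if not required.issubset(df.columns):
        raise ValueError(f"call table missing columns {required - set(df.columns)}")
    bad = ~df["call"].isin(CALLS)
    if bad.any():
        raise ValueError(f"unknown call values: {sorted(df.loc[bad, 'call'].unique())}")
    dup = df.duplicated(subset=["sample_id", "method"])
    if dup.any():
        raise ValueError("more than one call per (sample, method)")
    return df


def read_longitudinal(path) -> pd.DataFrame:
    """Read a longitudinal measurement CSV (patient_id, time, measure, value[, treatment])."""
    df = pd.read_csv(path)
    required = {"patient_id", "time", "measure", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"longitudinal table missing columns {required - set(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# classification


def classify_met_status(calls: pd.DataFrame) -> list[MetStatus]:
    """High/Low MET per sample from pMET IHC, with a FISH fallback.

    High iff IHC_pMET is positive, Low iff negative; only when the pMET IHC
    call is missing does FISH_GCN decide (positive amplification -> High).
    Samples with neither call are unclassifiable. The deciding assay is
    recorded as the basis; a FISH basis is never reported when a pMET IHC
    call exists.
    """
    wide = calls.pivot(index="sample_id", columns="method", values="call")
    out = []
    for sample in wide.index:
        pmet = wide.get("IHC_pMET", pd.Series(dtype=object)).get(sample, "missing")
        fish = wide.get("FISH_GCN", pd.Series(dtype=object)).get(sample, "missing")
        pmet = "missing" if pd.isna(pmet) else pmet
        fish = "missing" if pd.isna(fish) else fish
        if pmet != "missing":
            out.append(MetStatus(sample, "High" if pmet == "positive" else "Low",
                                 "pMET_IHC"))
        elif fish != "missing":
            out.append(MetStatus(sample, "High" if fish == "positive" else "Low",
                                 "FISH_amplification"))
        else:
            out.append(MetStatus(sample, "unclassifiable", None))
    return out


def binarize_continuous(
    values: pd.Series, threshold: float | None = None
) -> tuple[pd.Series, float | None, str | None]:
    """Binary positive/negative calls from a continuous measurement.

    With no explicit threshold, the cutpoint is found by an exhaustive 1-D
    two-cluster split minimizing total within-cluster sum of squares, and
    the threshold is the midpoint between the two clusters. Positive means
    value >= threshold. Identical values with no explicit threshold cannot
    be split: everything is called negative with a warning.
    """
    warning = None
    if threshold is None:
        if len(values) < 2:
            raise ValueError("need >= 2 samples to auto-derive a threshold")
        x = np.sort(values.to_numpy(float))
        if x[0] == x[-1]:
            return pd.Series("negative", index=values.index), None, \
                "all values identical; no threshold derivable, all called negative"
        best, best_cut = np.inf, None
        for i in range(1, len(x)):  # split after position i-1
            lo, hi = x[:i], x[i:]
            wss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if wss < best - 1e-12:
                best, best_cut = wss, (lo[-1] + hi[0]) / 2.0
        threshold = float(best_cut)
    calls = pd.Series(
        np.where(values.to_numpy(float) >= threshold, "positive", "negative"),
        index=values.index,
    )
    return calls, threshold, warning


# ---------------------------------------------------------------------------
# concordance


def pairwise_concordance(
    calls: pd.DataFrame, method_a: str, method_b: str, mode: str = "literal"
) -> tuple[float | None, int]:
    """Concordance between two detection methods over evaluable samples.

    With Npp both-positive, Nnn both-negative and Nd discordant:
    ``literal`` mode computes (Npp+Nnn) / (Npp+Nnn+2*Nd) — each discordant
    sample is counted in both the positive-by-either and negative-by-either
    denominators; ``agreement`` mode computes (Npp+Nnn) / (Npp+Nnn+Nd).
    Samples missing in either method are excluded. Returns (concordance,
    n_evaluable); concordance is None when nothing is evaluable.
    """
    if mode not in ("literal", "agreement"):
        raise ValueError("mode must be 'literal' or 'agreement'")
    wide = calls.pivot(index="sample_id", columns="method", values="call")
    for m in (method_a, method_b):
        if m not in wide.columns:
            return None, 0
    a, b = wide[method_a], wide[method_b]
    ok = a.isin(("positive", "negative")) & b.isin(("positive", "negative"))
    n = int(ok.sum())
    if n == 0:
        return None, 0
    a, b = a[ok], b[ok]
    npp = int(((a == "positive") & (b == "positive")).sum())
    nnn = int(((a == "negative") & (b == "negative")).sum())
    nd = n - npp - nnn
    denom = npp + nnn + (2 * nd if mode == "literal" else nd)
    if denom == 0:
        return None, n
    return (npp + nnn) / denom, n


def concordance_matrix(
    calls: pd.DataFrame, mode: str = "literal"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs concordance matrix (symmetric) with per-cell evaluable counts."""
    methods = sorted(calls["method"].unique())
    if len(methods) < 2:
        raise ValueError("need >= 2 methods")
    conc = pd.DataFrame(np.nan, index=methods, columns=methods)
    nev = pd.DataFrame(0, index=methods, columns=methods)
    for i, ma in enumerate(methods):
        for mb in methods[i:]:
            c, n = pairwise_concordance(calls, ma, mb, mode)
            if c is not None:
                conc.loc[ma, mb] = conc.loc[mb, ma] = c
            nev.loc[ma, mb] = nev.loc[mb, ma] = n
    return conc, nev


def plot_concordance_heatmap(conc: pd.DataFrame, path) -> None:
    """Render the concordance matrix as a heatmap PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(conc) + 2, 1.0 * len(conc) + 1.5))
    im = ax.imshow(conc.to_numpy(float), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(conc)), conc.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(conc)), conc.index)
    for i in range(len(conc)):
        for j in range(len(conc)):
            v = conc.iat[i, j]
            if not np.isnan(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="white" if v < 0.6 else "black", fontsize=8)
    fig.colorbar(im, ax=ax, label="concordance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# longitudinal tracking


def track_emergence(
    series: pd.DataFrame,
    baseline_window: int = 2,
    fold_threshold: float = 2.0,
    persistence: int = 1,
    value_col: str = "value",
    time_col: str = "time",
) -> dict:
    """Detect emergence of a marker above baseline in a longitudinal series.

    Baseline is the mean of the first ``baseline_window`` timepoints.
    Emergence is the first post-baseline timepoint whose value reaches
    ``fold_threshold`` x baseline (any positive value when the baseline is
    zero), sustained for ``persistence`` consecutive points (a trailing
    point counts as sustained if the series ends while still elevated).

    Returns {"emerged": bool, "time": first-emergence time or None,
    "baseline": float, "threshold_value": float}.
    """
    if baseline_window < 1:
        raise ValueError("baseline window must contain >= 1 timepoint")
    df = series.sort_values(time_col)
    times = df[time_col].to_numpy()
    if len(times) < 2:
        raise ValueError("need >= 2 timepoints")
    if (np.diff(times.astype(float)) <= 0).any():
        raise ValueError("timepoints must be strictly increasing")
    values = df[value_col].to_numpy(float)
    if baseline_window >= len(values):
        raise ValueError("baseline window must precede at least one tested point")
    baseline = float(values[:baseline_window].mean())
    cutoff = fold_threshold * baseline if baseline > 0 else 0.0
    elevated = values[baseline_window:] > cutoff if baseline == 0 else \
        values[baseline_window:] >= cutoff
    for i in range(len(elevated)):
        run = elevated[i: i + persistence]
        if len(run) < persistence:
            run = elevated[i:]
        if run.all() and elevated[i]:
            return {"emerged": True, "time": times[baseline_window + i],
                    "baseline": baseline, "threshold_value": cutoff}
    return {"emerged": False, "time": None, "baseline": baseline,
            "threshold_value": cutoff}
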