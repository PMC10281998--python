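"""Time-course DEG handling: expression filtering, DEG calling, time-point
cluster assignment and marker-set overlap enrichment.

The time-course design is a 6-point induction series (0, 12, 24, 36, 48,
72 h) with replicate TPM columns per time point. DEGs are assigned to the
time point where their expression peaks, provided the peak strictly exceeds
the mean of the remaining time points — genes flat across the course stay
unassigned. Cluster/marker relationships are quantified by one-sided
hypergeometric overlap tests with BH correction.

The built-in DEG caller (Welch t on log2(TPM + 0.5), BH) exists so synthetic
end-to-end runs need no external differential-expression tool; DEG tables
produced elsewhere are ingested as first-class input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import DEGRecord
from .stats import bh_adjust, hypergeom_upper_tail

__all__ = [
    "DEFAULT_TIMEPOINTS_H",
    "OverlapEnrichment",
    "expression_filter",
    "call_degs",
    "read_deg_table",
    "assign_time_clusters",
    "fisher_overlap",
    "relative_enrichment",
]

DEFAULT_TIMEPOINTS_H = (0, 12, 24, 36, 48, 72)


@dataclass(frozen=True)
class OverlapEnrichment:
    label: str
    overlap: int
    expected: float
    odds_ratio: float  # ad/bc from the 2x2 table; inf when bc == 0, ad > 0
    p_raw: float
    p_adj: float


def _group_means(
    table: pd.DataFrame, columns: Sequence[str], what: str
) -> pd.Series:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise KeyError(f"{what} columns absent from table: {missing}")
    return table[list(columns)].mean(axis=1)


def expression_filter(
    table: pd.DataFrame,
    control_cols: Sequence[str],
    treatment_cols: Sequence[str],
    min_mean_tpm: float = 1.0,
) -> list[str]:
    """Genes whose mean TPM strictly exceeds the cutoff in control OR treatment.

    ``table`` is gene (index) x sample (columns) TPM.
    """
    ctrl = _group_means(table, control_cols, "control")
    trt = _group_means(table, treatment_cols, "treatment")
    keep = (ctrl > min_mean_tpm) | (trt > min_mean_tpm)
    return table.index[keep].tolist()


def call_degs(
    table: pd.DataFrame,
    control_cols: Sequence[str],
    treatment_cols: Sequence[str],
    contrast: str,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_mean_tpm: float = 1.0,
    pseudocount: float = 0.5,
) -> list[DEGRecord]:
    """Simple built-in DEG caller over a TPM table.

    After the mean-TPM retention filter, the fold change is the ratio of
    pseudocount-added group means and significance is a two-sided Welch t on
    log2(TPM + pseudocount) with BH adjustment across retained genes. A gene
    is a DEG iff |FC| > fc_threshold and adjusted p < alpha. For published
    analyses an external DEG table (see :func:`read_deg_table`) replaces
    this path.
    """
    if len(control_cols) < 2 or len(treatment_cols) < 2:
        raise ValueError(
            "built-in DEG calling needs >=2 replicates per group; "
            "ingest an external DEG table instead"
        )
    retained = expression_filter(table, control_cols, treatment_cols, min_mean_tpm)
    sub = table.loc[retained]
    ctrl = sub[list(control_cols)].to_numpy(dtype=float)
    trt = sub[list(treatment_cols)].to_numpy(dtype=float)
    fc = (trt.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)
    log2fc = np.log2(fc)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = _st.ttest_ind(
            np.log2(trt + pseudocount),
            np.log2(ctrl + pseudocount),
            axis=1,
            equal_var=False,
        )
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    p_adj = np.asarray(bh_adjust(p.tolist()))
    out = []
    for gid, lfc, pa in zip(retained, log2fc, p_adj):
        if pa < alpha and (fc_threshold <= 0 or 2.0 ** abs(lfc) > fc_threshold):
            out.append(
                DEGRecord(
                    gene_id=gid,
                    contrast=contrast,
                    log2_fold_change=float(lfc),
                    adjusted_p=float(pa),
                    direction="up" if lfc >= 0 else "down",
                )
            )
    return out


def read_deg_table(path: str | Path, contrast: str) -> list[DEGRecord]:
    """Ingest an external DEG TSV with columns gene_id, log2_fold_change,
    adjusted_p (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2_fold_change", "adjusted_p"}
    if not required <= set(df.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    return [
        DEGRecord(
            gene_id=str(r.gene_id),
            contrast=contrast,
            log2_fold_change=float(r.log2_fold_change),
            adjusted_p=float(r.adjusted_p),
            direction="up" if r.log2_fold_change >= 0 else "down",
        )
        for r in df.itertuples()
    ]


def assign_time_clusters(
    deg_ids: Iterable[str],
    tpm: pd.DataFrame,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS_H,
) -> dict[str, int | None]:
    """Assign each DEG to the time point (hours) of its expression maximum.

    ``tpm`` holds one column per time point (mean over replicates), ordered
    as ``timepoints``. A gene is assigned only when its maximum strictly
    exceeds the arithmetic mean of the other time points; ties at the
    maximum resolve to the earliest time point. Unassigned genes map to None.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least two time points")
    if tpm.shape[1] != len(timepoints):
        raise ValueError(
            f"table has {tpm.shape[1]} columns for {len(timepoints)} time points"
        )
    out: dict[str, int | None] = {}
    values = tpm.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(tpm.index)}
    for gid in deg_ids:
        if gid not in index:
            raise KeyError(f"DEG {gid!r} absent from the TPM table")
        row = values[index[gid]]
        imax = int(np.argmax(row))  # argmax takes the first (earliest) max
        m = np.delete(row, imax).mean()
        # strict inequality, with a relative guard so that exactly-flat
        # profiles are never assigned through float rounding of the mean
        out[gid] = (
            int(timepoints[imax]) if row[imax] > m + 1e-9 * max(abs(m), 1.0)
            else None
        )
    return out


def fisher_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    label: str = "",
) -> OverlapEnrichment:
    """One-sided overlap test of two gene sets within a common universe.

    p = P(X >= |A∩B|) under Hypergeometric(N=|universe|, K=|A|, n=|B|);
    the odds ratio is ad/bc from the 2x2 membership table.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    stray = (A | B) - U
    if stray:
        raise ValueError(f"elements outside the universe: {sorted(stray)[:10]}")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(U) - a - b - c
    p = hypergeom_upper_tail(len(U), len(A), len(B), a)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return OverlapEnrichment(
        label=label,
        overlap=a,
        expected=len(A) * len(B) / len(U) if U else 0.0,
        odds_ratio=odds,
        p_raw=p,
        p_adj=p,
    )


def relative_enrichment(
    deg_set: Iterable[str],
    stage_marker_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[OverlapEnrichment]:
    """Observed/expected DEG counts in each stage marker set, BH-adjusted.

    expected = |DEG| * |markers| / |universe| per stage; one-sided
    hypergeometric p on the observed overlap.
    """
    U = set(universe)
    if not U:
        raise ValueError("empty universe")
    deg = set(deg_set)
    raw = [
        fisher_overlap(deg, set(markers), U, label=stage)
        for stage, markers in stage_marker_sets.items()
    ]
    p_adj = bh_adjust([r.p_raw for r in raw])
    return [
        OverlapEnrichment(r.label, r.overlap, r.expected, r.odds_ratio, r.p_raw, pa)
        for r, pa in zip(raw, p_adj)
    ]
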