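"""Cold-regulated gene classification from differential-expression tables.

A gene is *cold-induced* when its warm→cold log2 fold-change and FDR
q-value pass thresholds (default ≥ 1 log2, q ≤ 0.01).  The CBF-regulon
call additionally requires at least two-fold down-regulation of the gene
in the *cbf123* triple mutant at cold.  Percent reduction of induction in
the mutant is computed under two published conventions, both surfaced via
``criteria_version``:

``induction_ratio``
    100 × (1 − (mut_cold/mut_warm) / (wt_cold/wt_warm)) — how much of the
    *induction* survives loss of the CBF pathway.
``cold_expression_ratio``
    100 × (1 − mut_cold/wt_cold) — the straight expression ratio between
    genotypes at cold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegulonCall",
    "ReductionHistogram",
    "call_cold_induced",
    "reduction_percent",
    "call_regulon_membership",
    "classify_table",
    "bin_reductions",
    "summarize_first_wave",
]

INDUCTION_RATIO = "induction_ratio"
COLD_EXPRESSION_RATIO = "cold_expression_ratio"


@dataclass(frozen=True)
class RegulonCall:
    """Per-gene verdicts for one genotype."""

    gene_id: str
    genotype: str
    cold_induced: bool
    reduction_pct: float
    regulon_member: bool
    criteria_version: str = INDUCTION_RATIO

    def __post_init__(self) -> None:
        if not math.isnan(self.reduction_pct) and self.reduction_pct > 100:
            raise ValueError(
                f"{self.gene_id}: reduction_pct {self.reduction_pct} > 100"
            )
        if self.regulon_member and not self.cold_induced:
            raise ValueError(f"{self.gene_id}: member of the regulon but not induced")


def call_cold_induced(
    log2fc: float,
    q: float,
    fc_threshold_log2: float = 1.0,
    q_threshold: float = 0.01,
    allow_missing_q: bool = False,
) -> bool:
    """True iff the gene is cold-induced: log2fc ≥ threshold and q ≤ cutoff.

    Thresholds are inclusive ("at least two-fold"; "FDR = 0.01" read as a
    cutoff).  A missing q is an error unless ``allow_missing_q`` explicitly
    waives the FDR criterion.
    """
    if q is None or (isinstance(q, float) and math.isnan(q)):
        if not allow_missing_q:
            raise ValueError(
                "q-value missing; pass allow_missing_q=True to classify on "
                "fold-change alone"
            )
        return log2fc >= fc_threshold_log2
    return log2fc >= fc_threshold_log2 and q <= q_threshold


def reduction_percent(
    wt_cold: float,
    wt_warm: float,
    mut_cold: float,
    mut_warm: float,
    version: str = INDUCTION_RATIO,
    gene_id: str = "",
) -> float:
    """Percent reduction of a gene's cold response in the *cbf123* mutant."""
    label = f" for gene {gene_id}" if gene_id else ""
    if version == INDUCTION_RATIO:
        if min(wt_cold, wt_warm, mut_cold, mut_warm) <= 0:
            raise ValueError(f"non-positive abundance{label}")
        return 100.0 * (1.0 - (mut_cold / mut_warm) / (wt_cold / wt_warm))
    if version == COLD_EXPRESSION_RATIO:
        if wt_cold <= 0 or mut_cold < 0:
            raise ValueError(f"non-positive abundance{label}")
        return 100.0 * (1.0 - mut_cold / wt_cold)
    raise ValueError(f"unknown criteria_version {version!r}")


def call_regulon_membership(
    gene_id: str,
    genotype: str,
    cold_log2fc: float,
    cold_q: float,
    mut_log2ratio: float,
    mut_q: float,
    fc_threshold_log2: float = 1.0,
    q_threshold: float = 0.01,
    downregulation_log2: float = 1.0,
    mut_q_threshold: float | None = None,
    reduction_pct: float = float("nan"),
    criteria_version: str = COLD_EXPRESSION_RATIO,
) -> RegulonCall:
    """Call CBF-regulon membership for one gene in one genotype.

    ``mut_log2ratio`` is the WT-over-mutant log2 expression ratio at cold
    (positive when the gene is down in the mutant).  Membership requires
    cold induction AND ≥ ``downregulation_log2`` down-regulation at
    q ≤ ``mut_q_threshold`` (defaults to ``q_threshold``; the FDR cutoff is
    configurable per genotype because published regulon definitions differ,
    e.g. 0.01 for the Swedish/Italian ecotypes vs 0.05 for Col-0).
    """
    if mut_q_threshold is None:
        mut_q_threshold = q_threshold
    induced = call_cold_induced(cold_log2fc, cold_q, fc_threshold_log2, q_threshold)
    down = call_cold_induced(mut_log2ratio, mut_q, downregulation_log2,
                             mut_q_threshold)
    return RegulonCall(
        gene_id=gene_id,
        genotype=genotype,
        cold_induced=induced,
        reduction_pct=reduction_pct,
        regulon_member=bool(induced and down),
        criteria_version=criteria_version,
    )


def classify_table(
    de: pd.DataFrame,
    genotype: str,
    cold_contrast: str = "warm_vs_cold24h",
    mut_contrast: str = "wt_vs_mut_cold24h",
    fc_threshold_log2: float = 1.0,
    q_threshold: float = 0.01,
    downregulation_log2: float = 1.0,
    mut_q_threshold: float | None = None,
    reduction_version: str = INDUCTION_RATIO,
    allow_missing_q: bool = False,
) -> pd.DataFrame:
    """Classify every gene of one genotype in a long DE table.

    ``de`` needs columns gene_id, genotype, contrast, log2fc, q_value and —
    for reduction percentages — fpkm_ref/fpkm_alt on both contrasts
    (reference = warm or WT, alternative = cold or mutant).  Genes missing
    either contrast raise; the caller subsets first if that is intended.
    Returns one row per gene with cold_induced, reduction_pct,
    regulon_member and criteria_version columns.
    """
    sub = de[de["genotype"] == genotype]
    cold = sub[sub["contrast"] == cold_contrast].set_index("gene_id")
    mut = sub[sub["contrast"] == mut_contrast].set_index("gene_id")
    missing = set(cold.index).symmetric_difference(mut.index)
    if missing:
        raise ValueError(
            f"{genotype}: {len(missing)} gene(s) missing one of the contrasts "
            f"{cold_contrast!r}/{mut_contrast!r} (e.g. {sorted(missing)[:3]})"
        )
    rows = []
    for gid in cold.index:
        c, m = cold.loc[gid], mut.loc[gid]
        call = call_regulon_membership(
            gene_id=gid, genotype=genotype,
            cold_log2fc=float(c["log2fc"]), cold_q=float(c["q_value"]),
            mut_log2ratio=float(m["log2fc"]), mut_q=float(m["q_value"]),
            fc_threshold_log2=fc_threshold_log2, q_threshold=q_threshold,
            downregulation_log2=downregulation_log2,
            mut_q_threshold=mut_q_threshold,
            criteria_version=reduction_version,
        ) if not allow_missing_q else call_regulon_membership(
            # explicit override: q unknown, classify on fold change alone
            gene_id=gid, genotype=genotype,
            cold_log2fc=float(c["log2fc"]), cold_q=0.0,
            mut_log2ratio=float(m["log2fc"]), mut_q=0.0,
            fc_threshold_log2=fc_threshold_log2, q_threshold=1.0,
            downregulation_log2=downregulation_log2, mut_q_threshold=1.0,
            criteria_version=reduction_version,
        )
        red = float("nan")
        abunds = (m["fpkm_ref"], m["fpkm_alt"], c["fpkm_ref"], c["fpkm_alt"])
        if not any(pd.isna(a) for a in abunds):
            # mut contrast: ref = WT at cold, alt = mutant at cold;
            # cold contrast: ref = warm, alt = cold (wild type)
            wt_cold, mut_cold = float(m["fpkm_ref"]), float(m["fpkm_alt"])
            wt_warm = float(c["fpkm_ref"])
            if reduction_version == INDUCTION_RATIO:
                # mutant warm abundance approximated by WT warm when the
                # table does not carry a separate mutant-warm contrast
                mut_warm = wt_warm
                red = reduction_percent(wt_cold, wt_warm, mut_cold, mut_warm,
                                        INDUCTION_RATIO, gid)
            else:
                red = reduction_percent(wt_cold, 1.0, mut_cold, 1.0,
                                        COLD_EXPRESSION_RATIO, gid)
        rows.append(dict(
            gene_id=gid, genotype=genotype, cold_induced=call.cold_induced,
            reduction_pct=red, regulon_member=call.regulon_member,
            criteria_version=reduction_version,
        ))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReductionHistogram:
    """Histogram of percent reductions among cold-induced genes.

    Bins: (−∞, 0), [0, 10), …, [80, 90), [90, 100]; ``over50_count`` and
    ``over50_fraction`` summarise genes reduced strictly more than 50%.
    """

    bin_labels: tuple[str, ...]
    counts: tuple[int, ...]
    over50_count: int
    over50_fraction: float
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bin_labels, "count": self.counts})


def bin_reductions(reductions, bin_width: float = 10.0) -> ReductionHistogram:
    """Bin percent reductions for the regulon-impairment histograms."""
    vals = np.asarray(list(reductions), dtype=float)
    vals = vals[~np.isnan(vals)]
    if (vals > 100).any():
        raise ValueError("reduction_pct cannot exceed 100")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    labels = ["(-inf,0)"] + [
        f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 2)
    ] + [f"[{edges[-2]:g},{edges[-1]:g}]"]
    counts = [int(np.sum(vals < 0))]
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i < len(edges) - 2:
            counts.append(int(np.sum((vals >= lo) & (vals < hi))))
        else:
            counts.append(int(np.sum((vals >= lo) & (vals <= hi))))
    over50 = int(np.sum(vals > 50))
    n = int(vals.size)
    return ReductionHistogram(
        bin_labels=tuple(labels),
        counts=tuple(counts),
        over50_count=over50,
        over50_fraction=over50 / n if n else 0.0,
        n_total=n,
    )


def summarize_first_wave(panel: list[str], de: pd.DataFrame,
                         contrast: str = "warm_vs_cold24h") -> pd.DataFrame:
    """Cold-24h log2 fold-change matrix for a panel of rapidly cold-induced
    transcription-factor genes, gene × genotype, for reporting.

    Panel genes absent from a genotype's table are left NaN and listed in
    ``result.attrs['missing']``; nothing is imputed.
    """
    sub = de[de["contrast"] == contrast]
    mat = sub.pivot_table(index="gene_id", columns="genotype", values="log2fc",
                          aggfunc="first")
    out = mat.reindex(panel)
    missing = [
        (g, geno) for g in panel for geno in out.columns
        if pd.isna(out.loc[g, geno])
        and not ((sub["gene_id"] == g) & (sub["genotype"] == geno)).any()
    ]
    out.attrs["missing"] = missing
    return out
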