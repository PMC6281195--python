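"""Three-way regulon comparison and GO-term enrichment.

Regulon gene lists from three genotypes are partitioned into the seven
Venn regions (specific to one genotype, shared by a pair, common to all
three), and any region — or any gene set — can be tested for Gene
Ontology term enrichment with the hypergeometric upper-tail test against
a fixed genome background (default 33 278 nuclear genes, TAIR10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetPartition",
    "GOEnrichmentResult",
    "partition_three_sets",
    "hypergeometric_enrichment",
    "DEFAULT_BACKGROUND_N",
]

DEFAULT_BACKGROUND_N = 33278  # TAIR10 nuclear gene count

REGION_KEYS = ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")


@dataclass(frozen=True)
class GeneSetPartition:
    """The seven pairwise-disjoint Venn regions of three gene sets."""

    labels: tuple[str, str, str]
    regions: dict[str, frozenset[str]]
    input_sizes: tuple[int, int, int]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region_label(self, key: str) -> str:
        a, b, c = self.labels
        return {
            "a_only": f"{a} specific", "b_only": f"{b} specific",
            "c_only": f"{c} specific", "ab": f"{a} and {b}",
            "ac": f"{a} and {c}", "bc": f"{b} and {c}",
            "abc": "common to all three",
        }[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, self.region_label(k), len(self.regions[k])) for k in REGION_KEYS],
            columns=["region", "label", "n_genes"],
        )


def partition_three_sets(a, b, c, labels=("A", "B", "C")) -> GeneSetPartition:
    """Exact set algebra over three gene-id sets (ids case-normalized)."""
    A = {str(x).upper() for x in a}
    B = {str(x).upper() for x in b}
    C = {str(x).upper() for x in c}
    regions = {
        "a_only": frozenset(A - B - C),
        "b_only": frozenset(B - A - C),
        "c_only": frozenset(C - A - B),
        "ab": frozenset((A & B) - C),
        "ac": frozenset((A & C) - B),
        "bc": frozenset((B & C) - A),
        "abc": frozenset(A & B & C),
    }
    return GeneSetPartition(
        labels=tuple(labels),
        regions=regions,
        input_sizes=(len(A), len(B), len(C)),
    )


@dataclass(frozen=True)
class GOEnrichmentResult:
    term_id: str
    term_name: str
    target_count: int
    target_pct: float
    genome_count: int
    genome_pct: float
    p: float
    bh_q: float = float("nan")


def hypergeometric_enrichment(
    target,
    annotation: dict[str, set[str]],
    background_n: int = DEFAULT_BACKGROUND_N,
    term_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric upper-tail GO enrichment of ``target`` genes.

    For each term with at least one target gene, p is the probability of
    drawing ≥ k annotated genes in a sample of n = |target| from a
    background of ``background_n`` genes of which K carry the term.  Target
    genes absent from the annotation universe still count toward the draw
    size n (the background is the full nuclear gene set, not the annotated
    subset); their number is reported in ``result.attrs['n_unannotated']``.

    Tail probabilities are computed by scipy's hypergeometric survival
    function, which works in log space internally and is accurate down to
    the 1e-44 scale these tests reach.  Raw p is reported (sorted
    ascending); a Benjamini–Hochberg column is added for convenience but
    is not part of the classical report.
    """
    target = {str(x).upper() for x in target}
    n = len(target)
    if n == 0:
        raise ValueError("empty target set")
    term_names = term_names or {}
    universe = {str(g).upper() for genes in annotation.values() for g in genes}
    n_unannotated = len(target - universe)
    rows = []
    for term, genes in annotation.items():
        genes = {str(x).upper() for x in genes}
        K = len(genes)
        if K > background_n:
            raise ValueError(
                f"term {term}: {K} annotated genes exceed background_n={background_n}"
            )
        k = len(target & genes)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, background_n, K, n))
        rows.append(dict(
            term_id=term, term_name=term_names.get(term, ""),
            target_count=k, target_pct=100.0 * k / n,
            genome_count=K, genome_pct=100.0 * K / background_n,
            p=min(p, 1.0),
        ))
    df = pd.DataFrame(
        rows, columns=["term_id", "term_name", "target_count", "target_pct",
                       "genome_count", "genome_pct", "p"],
    ).sort_values("p", kind="stable").reset_index(drop=True)
    # Benjamini-Hochberg over the tested (k >= 1) terms
    m = len(df)
    if m:
        order = df["p"].to_numpy()
        q = order * m / (np.arange(m) + 1)
        df["bh_q"] = np.minimum.accumulate(q[::-1])[::-1].clip(max=1.0)
    else:
        df["bh_q"] = pd.Series(dtype=float)
    df.attrs["n_unannotated"] = n_unannotated
    df.attrs["n_target"] = n
    return df
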