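"""CRT/DRE promoter-motif counting and resampling enrichment test.

The CBF transcription factors bind the CRT/DRE element, core sequence
rCCGAC (r = A or G).  Enrichment of the motif in a gene set's promoters is
scored against a null built by repeatedly drawing random gene sets of the
same size from the whole promoter background, and reported as a Z-score
plus an empirical one-sided P value.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .io import PromoterSet

__all__ = [
    "MotifSpec",
    "MotifEnrichmentResult",
    "count_motif",
    "count_per_gene",
    "observed_per_gene",
    "enrichment_test",
]

DEFAULT_MOTIF_PATTERN = "RCCGAC"


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC DNA motif and the strand convention used when counting.

    ``sense_only`` counts matches on the promoter strand as extracted;
    ``both_strands`` additionally counts matches of the reverse-complement
    pattern on the same string.  Ambiguity codes in the *scanned sequence*
    never match (conservative counting).
    """

    pattern: str = DEFAULT_MOTIF_PATTERN
    strand_mode: str = "sense_only"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = set(self.pattern.upper()) - set(ambiguous_dna_values)
        if bad:
            raise ValueError(f"invalid IUPAC letters in pattern: {sorted(bad)}")
        if self.strand_mode not in ("sense_only", "both_strands"):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")

    def _regexes(self) -> list[re.Pattern]:
        pats = [self.pattern.upper()]
        if self.strand_mode == "both_strands":
            rc = str(Seq(self.pattern).reverse_complement()).upper()
            if rc != pats[0]:  # palindromic patterns would double-count
                pats.append(rc)
        out = []
        for p in pats:
            # lookahead so overlapping occurrences are all counted
            body = "".join(
                ch if len(ambiguous_dna_values[ch]) == 1
                else f"[{ambiguous_dna_values[ch]}]"
                for ch in p
            )
            out.append(re.compile(f"(?={body})"))
        return out


@dataclass(frozen=True)
class MotifEnrichmentResult:
    """Observed per-gene motif occurrence against a resampled null.

    ``empirical_p`` is the add-one estimator (1 + #{null ≥ observed}) /
    (n_samples + 1), one-sided for enrichment; ``z_tail_p`` is the upper
    normal-tail probability of ``z``, which can resolve far below the
    1/(n_samples+1) floor of the empirical estimate.
    """

    set_label: str
    set_size: int
    observed_per_gene: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    z_tail_p: float
    n_samples: int
    n_missing: int = 0


def count_motif(sequence: str, motif: MotifSpec | str = DEFAULT_MOTIF_PATTERN) -> int:
    """Count (possibly overlapping) IUPAC motif matches in one sequence.

    Scanning is case-insensitive; ambiguity codes in the sequence never
    match the pattern.
    """
    if isinstance(motif, str):
        motif = MotifSpec(pattern=motif)
    seq = sequence.upper()
    return sum(len(rx.findall(seq)) for rx in motif._regexes())


def count_per_gene(
    promoters: PromoterSet | dict[str, str],
    motif: MotifSpec | str = DEFAULT_MOTIF_PATTERN,
) -> dict[str, int]:
    """Motif count for every promoter; compute once, reuse for resampling."""
    if isinstance(motif, str):
        motif = MotifSpec(pattern=motif)
    seqs = promoters.sequences if isinstance(promoters, PromoterSet) else promoters
    regexes = motif._regexes()
    return {
        gid: sum(len(rx.findall(s.upper())) for rx in regexes)
        for gid, s in seqs.items()
    }


def _effective_set(counts: dict[str, int], gene_set) -> list[str]:
    gene_set = set(gene_set)
    present = [g for g in gene_set if g in counts]
    missing = len(gene_set) - len(present)
    if missing:
        warnings.warn(
            f"{missing} gene id(s) in the set have no promoter and were "
            f"excluded from motif scoring", stacklevel=3,
        )
    if not present:
        raise ValueError("no genes in the set have promoters to score")
    return present, missing


def observed_per_gene(
    promoters: PromoterSet | dict[str, str] | dict[str, int],
    gene_set,
    motif: MotifSpec | str = DEFAULT_MOTIF_PATTERN,
) -> float:
    """Mean motif occurrences per gene over a gene set.

    ``promoters`` may be a PromoterSet / id→sequence map, or a precomputed
    id→count map from :func:`count_per_gene`.
    """
    counts = _as_counts(promoters, motif)
    present, _ = _effective_set(counts, gene_set)
    return float(np.mean([counts[g] for g in present]))


def _as_counts(promoters, motif) -> dict[str, int]:
    if isinstance(promoters, dict) and promoters and all(
        isinstance(v, (int, np.integer)) for v in promoters.values()
    ):
        return promoters
    return count_per_gene(promoters, motif)


def enrichment_test(
    promoters: PromoterSet | dict[str, str] | dict[str, int],
    gene_set,
    motif: MotifSpec | str = DEFAULT_MOTIF_PATTERN,
    n_samples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    set_label: str = "",
) -> MotifEnrichmentResult:
    """Test motif enrichment in ``gene_set`` against random same-size sets.

    Each of ``n_samples`` null draws is a uniform sample *without
    replacement* of |gene_set| genes from all promoter-bearing genes
    (gene sets contain no duplicates); the statistic resampled is the
    per-gene mean occurrence.  With a fixed ``seed`` the result is exactly
    reproducible.

    When the null SD is zero, ``z`` is NaN (flagged by the caller seeing a
    non-finite value) but the empirical P is still reported.
    """
    counts = _as_counts(promoters, motif)
    if len(set(gene_set)) > len(counts):
        raise ValueError("gene set larger than the promoter background")
    present, n_missing = _effective_set(counts, gene_set)
    k = len(present)
    background = np.fromiter(counts.values(), dtype=float, count=len(counts))

    observed = float(np.mean([counts[g] for g in present]))
    if rng is None:
        rng = np.random.default_rng(seed)
    null = np.empty(n_samples, dtype=float)
    for i in range(n_samples):
        idx = rng.choice(background.size, size=k, replace=False)
        null[i] = background[idx].mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_samples > 1 else 0.0
    if null_sd > 0:
        z = (observed - null_mean) / null_sd
        z_tail_p = float(stats.norm.sf(z))
    else:
        z, z_tail_p = float("nan"), float("nan")
    empirical_p = (1 + int(np.sum(null >= observed))) / (n_samples + 1)
    return MotifEnrichmentResult(
        set_label=set_label or f"set(n={k})",
        set_size=k,
        observed_per_gene=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        empirical_p=float(empirical_p),
        z_tail_p=z_tail_p,
        n_samples=n_samples,
        n_missing=n_missing,
    )
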