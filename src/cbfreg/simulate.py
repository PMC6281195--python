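"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the structure of a cold-acclimation study on
Arabidopsis ecotypes: logistic electrolyte-leakage curves with known EL50s,
differential-expression tables with planted gene classes (CBF-dependent,
CBF-coregulated, CBF-independent cold-regulated, and non-cold-regulated),
promoter sets with controlled CRT/DRE (rCCGAC) motif rates plus a matching
single-contig genome and annotation for round-trip testing, and a genotype
panel with a known regulon-size/climate relationship.

Every artifact type draws from its own pseudo-random stream spawned from
the single configured seed, so regenerating one artifact never perturbs
the others, and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .freeze import LeakageCurve, curves_from_dataframe
from .io import GeneModel, PromoterSet, reverse_complement

__all__ = [
    "SimulationConfig",
    "LeakageExperiment",
    "ExpressionTables",
    "PromoterSimulation",
    "generate_leakage_experiment",
    "generate_expression_tables",
    "generate_promoter_set",
    "default_climate_panel",
]

GENE_CLASSES = ("cbf_dependent", "coregulated", "cbf_independent_cor", "non_cor")

_MOTIF_CORE = "CCGAC"
_MOTIF_LEN = 6

# per-artifact pseudo-random streams spawned from the one seed
_STREAM_LEAKAGE, _STREAM_EXPRESSION, _STREAM_PROMOTERS = 0, 1, 2


def _default_class_fractions() -> dict[str, float]:
    return {
        "cbf_dependent": 0.05,
        "coregulated": 0.05,
        "cbf_independent_cor": 0.05,
        "non_cor": 0.85,
    }


def _default_induction_ranges() -> dict[str, tuple[float, float]]:
    return {
        "cbf_dependent": (2.0, 5.0),
        "coregulated": (1.5, 4.0),
        "cbf_independent_cor": (1.0, 3.0),
        "non_cor": (-0.5, 0.5),
    }


def _default_reduction_ranges() -> dict[str, tuple[float, float]]:
    # linear fraction of the cold induction lost in the cbf123 mutant
    return {
        "cbf_dependent": (0.75, 0.95),
        "coregulated": (0.30, 0.45),
        "cbf_independent_cor": (-0.10, 0.10),
        "non_cor": (-0.10, 0.10),
    }


def _default_el50_map() -> dict[tuple[str, str], float]:
    # wild-type ecotypes and their cbf123 triple mutants; values are the
    # EL50 conditions the generator reproduces
    return {
        ("SW", "non_acclimated"): -5.1,
        ("SW", "cold_acclimated"): -12.4,
        ("sw_cbf123", "non_acclimated"): -4.5,
        ("sw_cbf123", "cold_acclimated"): -8.9,
        ("IT", "non_acclimated"): -4.7,
        ("IT", "cold_acclimated"): -8.7,
        ("it_cbf123", "non_acclimated"): -3.8,
        ("it_cbf123", "cold_acclimated"): -7.3,
    }


def _default_composition() -> dict[str, float]:
    return {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the
    emulated experimental design (3 replicates, ~0.28 background motifs
    per 1-kb promoter, planted EL50s spanning −12.4 to −3.8 °C)."""

    seed: int = 0
    n_genes: int = 2000
    class_fractions: dict[str, float] = field(default_factory=_default_class_fractions)
    induction_log2fc_range: dict[str, tuple[float, float]] = field(
        default_factory=_default_induction_ranges)
    mutant_reduction_range: dict[str, tuple[float, float]] = field(
        default_factory=_default_reduction_ranges)
    promoter_length: int = 1000
    background_motif_rate: float = 0.28
    planted_motif_rate: float = 2.0
    promoter_base_composition: dict[str, float] = field(
        default_factory=_default_composition)
    leakage_el50_by_group: dict[tuple[str, str], float] = field(
        default_factory=_default_el50_map)
    leakage_slope: float = 1.5
    leakage_noise_sd: float = 3.0
    replicates: int = 3
    test_temperatures: tuple[float, ...] = (
        -18.0, -16.0, -14.0, -12.0, -10.0, -8.0, -6.0, -4.0, -2.0, 0.0)
    genotypes: tuple[str, ...] = ("SW", "IT")

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {sorted(unknown)}")
        if self.background_motif_rate < 0 or self.planted_motif_rate < 0:
            raise ValueError("motif rates must be >= 0")
        if self.leakage_noise_sd < 0:
            raise ValueError("leakage_noise_sd must be >= 0")
        if self.promoter_length <= _MOTIF_LEN:
            raise ValueError("promoter_length must exceed the motif length")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        comp_total = sum(self.promoter_base_composition.values())
        if abs(comp_total - 1.0) > 1e-9:
            raise ValueError("promoter_base_composition must sum to 1")
        for cls, (lo, hi) in self.mutant_reduction_range.items():
            if hi >= 1.0:
                raise ValueError(f"{cls}: reduction fraction must stay below 1")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,)))

    # --- flat YAML-style config round trip -------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["leakage_el50_by_group"] = {
            f"{g}|{a}": v for (g, a), v in self.leakage_el50_by_group.items()}
        d["test_temperatures"] = list(self.test_temperatures)
        d["genotypes"] = list(self.genotypes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["leakage_el50_by_group"] = {
            tuple(k.split("|")): float(v)
            for k, v in d["leakage_el50_by_group"].items()}
        d["test_temperatures"] = tuple(d["test_temperatures"])
        d["genotypes"] = tuple(d["genotypes"])
        for key in ("induction_log2fc_range", "mutant_reduction_range"):
            d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# electrolyte leakage


@dataclass
class LeakageExperiment:
    """Replicate-level leakage table, per-group mean curves, and truth."""

    data: pd.DataFrame  # genotype, acclimation, temperature_C, replicate, leakage_pct
    curves: list[LeakageCurve]
    true_el50: dict[tuple[str, str], float]
    extrapolated_groups: set[tuple[str, str]]


def logistic_leakage(temperature, el50: float, slope: float):
    """Mean % leakage: 100 / (1 + exp((T − EL50)/s)) — 50% exactly at EL50,
    → 100 far below, → 0 far above."""
    t = np.asarray(temperature, dtype=float)
    return 100.0 / (1.0 + np.exp((t - el50) / slope))


def generate_leakage_experiment(config: SimulationConfig) -> LeakageExperiment:
    """Simulate the freeze-test: logistic response plus truncated Gaussian
    replicate noise for every (genotype, acclimation) group.

    Groups whose EL50 lies outside the tested temperature span are flagged
    (the downstream cubic fit will extrapolate for them) rather than
    rejected.
    """
    rng = config._rng(_STREAM_LEAKAGE)
    temps = np.asarray(config.test_temperatures, dtype=float)
    tmin, tmax = temps.min(), temps.max()
    rows = []
    flagged: set[tuple[str, str]] = set()
    for (geno, acc), el50 in sorted(config.leakage_el50_by_group.items()):
        if not tmin <= el50 <= tmax:
            flagged.add((geno, acc))
        mean = logistic_leakage(temps, el50, config.leakage_slope)
        for rep in range(1, config.replicates + 1):
            noise = rng.normal(0.0, config.leakage_noise_sd, size=temps.size) \
                if config.leakage_noise_sd > 0 else np.zeros(temps.size)
            leak = np.clip(mean + noise, 0.0, 100.0)
            for t, v in zip(temps, leak):
                rows.append((geno, acc, float(t), rep, float(v)))
    data = pd.DataFrame(
        rows, columns=["genotype", "acclimation", "temperature_C",
                       "replicate", "leakage_pct"])
    return LeakageExperiment(
        data=data,
        curves=curves_from_dataframe(data),
        true_el50=dict(config.leakage_el50_by_group),
        extrapolated_groups=flagged,
    )


# ---------------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionTables:
    """Long-format DE table over all genotypes/contrasts plus ground truth.

    ``de`` columns: genotype, contrast, gene_id, log2fc, q_value, fpkm_ref,
    fpkm_alt (reference = warm or wild type; alternative = cold or mutant).
    ``truth`` columns: genotype, gene_id, gene_class, induced_24h,
    induced_2wk, reduction_frac, regulon_member.
    """

    de: pd.DataFrame
    truth: pd.DataFrame


def _assign_classes(config: SimulationConfig) -> list[str]:
    counts = {}
    remaining = config.n_genes
    items = [(c, config.class_fractions.get(c, 0.0)) for c in GENE_CLASSES]
    for cls, frac in items[:-1]:
        counts[cls] = int(round(frac * config.n_genes))
        remaining -= counts[cls]
    counts[items[-1][0]] = remaining
    if min(counts.values()) < 0:
        raise ValueError("class fractions produce a negative class size")
    labels = []
    for cls in GENE_CLASSES:
        labels.extend([cls] * counts[cls])
    return labels[: config.n_genes]


def _q_for(rng, significant: np.ndarray) -> np.ndarray:
    """FDR q-values generated directly: well below the 0.01 cutoff for true
    effects, diffuse above it otherwise (the DE engine itself is out of
    scope; only the filtering logic is exercised)."""
    q = rng.uniform(0.02, 1.0, size=significant.size)
    q[significant] = rng.uniform(1e-6, 0.009, size=int(significant.sum()))
    return q


def generate_expression_tables(config: SimulationConfig) -> ExpressionTables:
    """Plant per-class cold inductions and mutant reductions and emit DE
    tables for the warm→cold (24 h and 2 wk) and WT-vs-mutant-at-cold
    contrasts of every configured genotype.

    The mutant's warm-temperature abundance equals the wild type's (the
    CBF pathway is inactive at warm temperature), so the planted reduction
    fraction is recovered identically by both reduction conventions.
    """
    rng = config._rng(_STREAM_EXPRESSION)
    classes = np.array(_assign_classes(config))
    gene_ids = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    de_rows = []
    truth_rows = []
    for geno in config.genotypes:
        warm = np.maximum(rng.lognormal(mean=2.0, sigma=1.0, size=config.n_genes), 1.0)
        fc24 = np.empty(config.n_genes)
        red = np.empty(config.n_genes)
        for cls in GENE_CLASSES:
            mask = classes == cls
            lo, hi = config.induction_log2fc_range[cls]
            fc24[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
            rlo, rhi = config.mutant_reduction_range[cls]
            red[mask] = rng.uniform(rlo, rhi, size=int(mask.sum()))
        induced_cls = np.isin(classes, GENE_CLASSES[:3])
        q24 = _q_for(rng, induced_cls)
        wt_cold = warm * np.exp2(fc24)
        mut_cold = wt_cold * (1.0 - red)
        mut_log2 = np.log2(wt_cold / mut_cold)
        q_mut = _q_for(rng, np.abs(mut_log2) >= 1.0)

        # at 2 weeks a fraction of the induced genes has relaxed to baseline
        stays = rng.random(config.n_genes) < 0.65
        induced_2wk = induced_cls & stays
        fc2wk = np.where(induced_2wk, fc24, rng.uniform(-0.5, 0.5, config.n_genes))
        q2wk = _q_for(rng, induced_2wk)
        wt_cold2 = warm * np.exp2(fc2wk)
        mut_cold2 = wt_cold2 * (1.0 - red)
        mut2_log2 = np.log2(wt_cold2 / mut_cold2)
        q_mut2 = _q_for(rng, np.abs(mut2_log2) >= 1.0)

        for contrast, fc, q, ref, alt in (
            ("warm_vs_cold24h", fc24, q24, warm, wt_cold),
            ("wt_vs_mut_cold24h", mut_log2, q_mut, wt_cold, mut_cold),
            ("warm_vs_cold2wk", fc2wk, q2wk, warm, wt_cold2),
            ("wt_vs_mut_cold2wk", mut2_log2, q_mut2, wt_cold2, mut_cold2),
        ):
            de_rows.append(pd.DataFrame(dict(
                genotype=geno, contrast=contrast, gene_id=gene_ids,
                log2fc=fc, q_value=q, fpkm_ref=ref, fpkm_alt=alt)))
        induced24 = induced_cls & (fc24 >= 1.0) & (q24 <= 0.01)
        member = induced24 & (mut_log2 >= 1.0) & (q_mut <= 0.01)
        truth_rows.append(pd.DataFrame(dict(
            genotype=geno, gene_id=gene_ids, gene_class=classes,
            induced_24h=induced24, induced_2wk=induced_2wk & (q2wk <= 0.01),
            reduction_frac=red, regulon_member=member)))
    return ExpressionTables(
        de=pd.concat(de_rows, ignore_index=True),
        truth=pd.concat(truth_rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# promoters / genome / annotation


@dataclass
class PromoterSimulation:
    """Planted promoter set plus a matching genome and gene models.

    ``planted_counts`` is the number of deliberately inserted rCCGAC
    instances per gene (spontaneous occurrences from the random base
    composition come on top; with uniform 25% composition the spontaneous
    rate is 2 × 4⁻⁶ per position per matching first base, ≈ 0.49 expected
    per 1-kb promoter)."""

    promoters: PromoterSet
    genome: dict[str, str]
    models: list[GeneModel]
    planted_counts: dict[str, int]
    target_genes: frozenset[str]


def _random_sequence(rng, length: int, composition: dict[str, float]) -> np.ndarray:
    bases = np.array(sorted(composition))
    probs = np.array([composition[b] for b in sorted(composition)])
    return rng.choice(bases, size=length, p=probs)


def _plant_motifs(rng, seq: np.ndarray, n_motifs: int) -> int:
    """Insert n non-overlapping rCCGAC instances at uniform positions."""
    length = len(seq)
    if n_motifs * _MOTIF_LEN > length:
        raise ValueError(
            f"cannot place {n_motifs} non-overlapping motifs in {length} bases")
    occupied: list[tuple[int, int]] = []
    placed = 0
    attempts = 0
    while placed < n_motifs:
        attempts += 1
        if attempts > 1000 * n_motifs:
            raise ValueError("motif placement rejection sampling failed")
        start = int(rng.integers(0, length - _MOTIF_LEN + 1))
        if any(start < e and start + _MOTIF_LEN > s for s, e in occupied):
            continue
        r_base = "A" if rng.random() < 0.5 else "G"
        seq[start:start + _MOTIF_LEN] = list(r_base + _MOTIF_CORE)
        occupied.append((start, start + _MOTIF_LEN))
        placed += 1
    return placed


_SPACER = "TTTTT"


def generate_promoter_set(
    config: SimulationConfig,
    target_genes=None,
    n_genes: int | None = None,
) -> PromoterSimulation:
    """Generate promoters with Poisson-planted motif counts and emit a
    matching single-contig genome FASTA layout plus BED-convention gene
    models (strands alternate so both extraction paths are exercised).

    ``target_genes`` get ``planted_motif_rate`` expected insertions,
    everything else ``background_motif_rate``.
    """
    rng = config._rng(_STREAM_PROMOTERS)
    n = n_genes if n_genes is not None else config.n_genes
    ids = [f"G{i:05d}" for i in range(n)]
    targets = frozenset(str(g) for g in (target_genes or ()))
    unknown = targets - set(ids)
    if unknown:
        raise ValueError(f"target gene(s) not generated: {sorted(unknown)[:3]}")

    seqs: dict[str, str] = {}
    planted: dict[str, int] = {}
    genome_parts: list[str] = []
    models: list[GeneModel] = []
    offset = 0  # 0-based running position in the contig
    contig = "chrSim"
    for i, gid in enumerate(ids):
        rate = config.planted_motif_rate if gid in targets else \
            config.background_motif_rate
        n_mot = int(rng.poisson(rate))
        seq = _random_sequence(rng, config.promoter_length, config.promoter_base_composition)
        planted[gid] = _plant_motifs(rng, seq, n_mot)
        promoter = "".join(seq)
        seqs[gid] = promoter
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            # [promoter][ATG...]: translation starts right after the window
            genome_parts.append(promoter + "ATG")
            ts = offset + config.promoter_length + 1  # 1-based
            offset += config.promoter_length + 3
        else:
            # reverse-strand gene: genome carries CAT (revcomp of ATG) then
            # the reverse complement of the promoter
            genome_parts.append("CAT" + reverse_complement(promoter))
            ts = offset + 3  # 1-based position of the start-codon base
            offset += config.promoter_length + 3
        genome_parts.append(_SPACER)
        offset += len(_SPACER)
        models.append(GeneModel(gene_id=gid, contig=contig,
                                translation_start=ts, strand=strand))
    genome = {contig: "".join(genome_parts)}
    promoters = PromoterSet(
        sequences=seqs,
        requested_length=config.promoter_length,
        provenance=f"synthetic (seed={config.seed}, n={n})",
    )
    return PromoterSimulation(
        promoters=promoters, genome=genome, models=models,
        planted_counts=planted, target_genes=targets,
    )


# ---------------------------------------------------------------------------
# genotype/climate panel


def default_climate_panel() -> pd.DataFrame:
    """Genotype panel with source-habitat minimum monthly low temperature
    and regulon/COR gene counts exhibiting the expected inverse
    relationship (colder site → larger regulon)."""
    return pd.DataFrame(
        dict(
            genotype=["IT", "Col-0", "SW"],
            min_monthly_low=[2.7, -5.0, -12.6],
            regulon_count=[112, 321, 421],
            cor_count=[1567, 3346, 4705],
        )
    )
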