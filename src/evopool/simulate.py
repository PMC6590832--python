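"""Synthetic experimental-evolution cohort generator.

Emulates the statistical structure of a bottleneck/experimental-evolution
study on *Drosophila*-like lines: a mass-bred base population supplies
founder allele frequencies; each line drifts through a designed series of
small bottlenecks (Wright-Fisher binomial resampling at the realized
breeder census) and a flush back to a large census; pooled
genotyping-by-sequencing of 15 males per line produces per-locus
coverage/variant-count tables; and ten generations of rearing on a
stressful medium produce trait trajectories whose per-line response is
coupled to retained diversity, an extinction rule (fewer than 200 adults
collected), and before/after egg-to-adult viability on stress and benign
media with a diversity-independent benign cost.

Two drift engines are provided.  ``simulate_drift`` is the frequency-level
binomial Wright-Fisher chain used for cohorts; its exact oracle is
``pedigree.expected_het_retention``.  ``simulate_pair_mating_ibd`` is a
genealogical simulator of four adults mating at random without selfing;
its within-individual autozygosity follows the two-generation-memory F
recursion exactly and serves as the recursion's calibration counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import BottleneckDesign, PAPER_DESIGNS

__all__ = [
    "FounderPool",
    "LineConfig",
    "SimulatedLine",
    "PhenotypeParams",
    "CohortConfig",
    "Cohort",
    "make_founder_pool",
    "simulate_drift",
    "simulate_pair_mating_ibd",
    "simulate_pool_reads",
    "simulate_phenotypes",
    "generate_cohort",
    "write_cohort",
]

AUTOSOMES = ("2", "3", "4")
CHROMOSOMES = ("2", "3", "4", "X")
#: Rough chromosome-arm weight of the fly genome (tiny dot chromosome 4,
#: a real X fraction so the autosome filter is exercised downstream).
DEFAULT_CHROM_WEIGHTS: dict[str, float] = {"2": 0.38, "3": 0.40, "4": 0.02, "X": 0.20}


# ---------------------------------------------------------------------------
# founder pool
# ---------------------------------------------------------------------------

@dataclass
class FounderPool:
    """Founder (base-population) variant loci and their frequencies."""

    loci: pd.DataFrame  # columns: chrom, pos, p0

    @property
    def p0(self) -> np.ndarray:
        return self.loci["p0"].to_numpy()

    @property
    def founder_het(self) -> float:
        """Sigma p0 (1 - p0) over all founder loci."""
        p = self.p0
        return float(np.sum(p * (1.0 - p)))

    def __len__(self) -> int:
        return len(self.loci)


def make_founder_pool(
    n_loci: int,
    freq_law: tuple = ("beta", 0.5, 0.5),
    chrom_weights: Mapping[str, float] | None = None,
    trunc: tuple[float, float] = (0.05, 0.95),
    seed: int | np.random.SeedSequence = 0,
) -> FounderPool:
    """Draw founder loci i.i.d. from a frequency law.

    The default symmetric Beta(0.5, 0.5), truncated to [0.05, 0.95],
    mimics the U-shaped site-frequency spectrum of a large outbred base
    while keeping every founder locus genuinely polymorphic.

    ``freq_law`` is ``("beta", a, b)`` or ``("point", p)``.
    """
    if n_loci < 1:
        raise ValueError(f"n_loci must be >= 1, got {n_loci}")
    weights = dict(DEFAULT_CHROM_WEIGHTS if chrom_weights is None else chrom_weights)
    w = np.array([weights.get(c, 0.0) for c in CHROMOSOMES], dtype=float)
    if w.sum() <= 0:
        raise ValueError("chrom_weights must have positive total weight")
    w = w / w.sum()
    rng = np.random.default_rng(seed)

    kind = freq_law[0]
    if kind == "beta":
        a, b = float(freq_law[1]), float(freq_law[2])
        if a <= 0 or b <= 0:
            raise ValueError(f"beta shapes must be positive, got {freq_law}")
        p0 = rng.beta(a, b, size=n_loci)
        p0 = np.clip(p0, trunc[0], trunc[1])
    elif kind == "point":
        p = float(freq_law[1])
        if not 0.0 < p < 1.0:
            raise ValueError(f"point mass must lie in (0,1), got {p}")
        p0 = np.full(n_loci, p)
    else:
        raise ValueError(f"unknown freq_law {freq_law!r}")

    chrom = rng.choice(np.array(CHROMOSOMES), size=n_loci, p=w)
    # strictly increasing positions within each chromosome
    pos = np.empty(n_loci, dtype=np.int64)
    for c in CHROMOSOMES:
        mask = chrom == c
        n = int(mask.sum())
        if n:
            gaps = rng.integers(50, 5000, size=n)
            pos[mask] = np.cumsum(gaps)
    loci = pd.DataFrame({"chrom": chrom, "pos": pos, "p0": p0})
    loci = loci.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return FounderPool(loci=loci)


# ---------------------------------------------------------------------------
# drift engines
# ---------------------------------------------------------------------------

def _drift_chain(p: np.ndarray, copies: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Binomial WF resampling of per-locus frequencies.

    ``copies`` lists the gene-copy count (2 Ne) of each successive
    generation; every locus is resampled independently as
    Binomial(k, p)/k for each k in the list.
    """
    p = np.asarray(p, dtype=float).copy()
    for k in copies:
        p = rng.binomial(int(k), p) / float(k)
    return p


def simulate_drift(
    pool: FounderPool | np.ndarray,
    design: BottleneckDesign,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    n_flush_gens: int = 2,
    census_trajectory: Sequence[int] | None = None,
) -> np.ndarray:
    """Neutral Wright-Fisher drift of founder frequencies through a design.

    Each generation with census N resamples every locus independently as
    Binomial(2N, p)/2N; loci may fix at 0 or 1 (absorbing).  Founding the
    line from the large mass-bred base is treated as frequency-preserving
    (the founders are unrelated), so the bottleneck phase contributes
    ``design.recursion_steps()`` drift generations at the bottleneck
    census, followed by ``n_flush_gens`` generations at the flush census.
    ``census_trajectory`` overrides the whole per-generation census list
    (used by the cohort generator for realized breeder counts).
    """
    p0 = pool.p0 if isinstance(pool, FounderPool) else np.asarray(pool, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if census_trajectory is None:
        census_trajectory = [design.bottleneck_size] * design.recursion_steps() + [
            design.flush_size
        ] * n_flush_gens
    return _drift_chain(p0, [2 * int(n) for n in census_trajectory], rng)


def simulate_pair_mating_ibd(
    n_steps: int,
    n_replicates: int,
    n_adults: int = 4,
    seed: int | np.random.SeedSequence = 0,
    return_replicates: bool = False,
) -> float | np.ndarray:
    """Monte-Carlo realization of the two-generation-memory F recursion.

    Simulates ``n_replicates`` independent loci-lines of ``n_adults``
    diploid adults; each generation every offspring draws two *distinct*
    parents uniformly and one random allele from each (random mating,
    selfing excluded) — the mating system whose within-individual
    autozygosity obeys F_t = F_{t-1} + (1 - 2F_{t-1} + F_{t-2})/(2Ne).
    The recursion's initial condition F_0 = F_{-1} = 0 describes a
    population *already breeding at census N*: two distinct generation-0
    individuals share alleles identical by descent with probability
    1/(2N).  Starting from a fully unrelated gamete pool therefore takes
    ``n_steps + 1`` matings to reach recursion step ``n_steps``, which is
    what this function runs.

    Returns the fraction of autozygous individuals in the final
    generation, an unbiased estimate of F at step ``n_steps``; with
    ``return_replicates=True`` the per-replicate fractions instead
    (individuals within a replicate share a genealogy, so Monte-Carlo
    error should be assessed across replicates).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = np.random.default_rng(seed)
    m, k = n_replicates, n_adults
    labels = np.broadcast_to(np.arange(2 * k).reshape(1, k, 2), (m, k, 2)).copy()
    rows = np.arange(m)[:, None]
    for _ in range(n_steps + 1):
        parent1 = rng.integers(0, k, size=(m, k))
        parent2 = (parent1 + rng.integers(1, k, size=(m, k))) % k
        a1 = rng.integers(0, 2, size=(m, k))
        a2 = rng.integers(0, 2, size=(m, k))
        labels = np.stack(
            [labels[rows, parent1, a1], labels[rows, parent2, a2]], axis=2
        )
    auto = np.mean(labels[:, :, 0] == labels[:, :, 1], axis=1)
    if return_replicates:
        return auto
    return float(auto.mean())


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------

def simulate_pool_reads(
    freqs: np.ndarray,
    loci: pd.DataFrame | None = None,
    n_males: int = 15,
    depth_law: tuple = ("nbinom", 3.0, 45.0),
    max_cov: int = 600,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pooled-GBS read table for one line.

    Per locus: 2 * n_males gene copies are sampled from the line (pool
    frequency q), coverage c is drawn from the depth law (default a
    negative binomial with dispersion 3 and mean 45, mode near 30,
    clipped to [0, max_cov]), and the variant read count is
    Binomial(c, q).  Male X hemizygosity is not modelled; X loci are
    removed by the downstream autosome filter anyway.

    Returns a DataFrame with columns chrom, pos, coverage, variant_count,
    frequency (rows with zero coverage are dropped).
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = freqs.size
    copies = 2 * n_males
    q = rng.binomial(copies, freqs) / copies

    kind = depth_law[0]
    if kind == "nbinom":
        r, mean = float(depth_law[1]), float(depth_law[2])
        if r <= 0 or mean < 0:
            raise ValueError(f"invalid depth_law {depth_law!r}")
        if mean == 0:
            cov = np.zeros(n, dtype=int)
        else:
            cov = rng.negative_binomial(r, r / (r + mean), size=n)
    elif kind == "point":
        cov = np.full(n, int(depth_law[1]))
    else:
        raise ValueError(f"unknown depth_law {depth_law!r}")
    cov = np.minimum(cov, max_cov)

    var = rng.binomial(cov, q)
    if loci is None:
        table = pd.DataFrame(
            {"chrom": "2", "pos": np.arange(1, n + 1), "coverage": cov, "variant_count": var}
        )
    else:
        table = pd.DataFrame(
            {
                "chrom": loci["chrom"].to_numpy(),
                "pos": loci["pos"].to_numpy(),
                "coverage": cov,
                "variant_count": var,
            }
        )
    table = table[table["coverage"] > 0].reset_index(drop=True)
    table["frequency"] = table["variant_count"] / table["coverage"]
    return table


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeParams:
    """Trait-model parameters of the stated synthetic world.

    Trait means follow ``baseline + beta * (relative retained het) * g``
    with Gaussian noise on the trait scale; viability counts are binomial
    over the assayed eggs.  ``benign_cost`` is deliberately identical for
    every line (independent of diversity): adaptation carries a similar
    cost regardless of how fast a line responds, so diversity predicts the
    stress-medium change but not the benign one.
    """

    productivity_baseline: float = 2.0  # flies per female per day
    productivity_beta: float = 0.15  # per generation at full diversity
    productivity_sd: float = 0.25
    body_mass_baseline: float = 0.25  # mg
    body_mass_beta: float = 0.005
    body_mass_ind_sd: float = 0.03  # among the 15 weighed males
    n_males_weighed: int = 15
    stress_v0_mean: float = 0.5  # baseline assay targets ~50 % survival
    stress_v0_sd: float = 0.05
    benign_v0_mean: float = 0.85
    benign_v0_sd: float = 0.04
    stress_gain: float = 0.30  # viability gain over 10 gens at full diversity
    benign_cost: float = 0.02  # uniform cost, diversity-independent
    eggs_gen0: int = 75  # 5 vials x 15 eggs
    eggs_gen10: int = 150  # 10 vials x 15 eggs
    out_base: float = 190.0  # adult output model vs the 200-fly rule
    out_gain: float = 155.0
    out_sd: float = 50.0
    n_generations: int = 10

    def __post_init__(self) -> None:
        for name in (
            "productivity_beta", "productivity_sd", "body_mass_beta",
            "body_mass_ind_sd", "stress_v0_sd", "benign_v0_sd",
            "stress_gain", "benign_cost", "out_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LineConfig:
    """Identity and treatment of one experimental line."""

    line_id: str
    group: str  # OB / Low / Medium / High
    design: BottleneckDesign | None
    acid_level: float  # mL/L acetic acid (1.0 or 2.5)
    seed: int

    def __post_init__(self) -> None:
        expected = {"Low": 2, "Medium": 3, "High": 5}
        if self.group == "OB":
            if self.design is not None:
                raise ValueError("outbred lines carry no bottleneck design")
        elif self.group in expected:
            if self.design is None or self.design.n_bottleneck_gens != expected[self.group]:
                raise ValueError(
                    f"group {self.group} requires {expected[self.group]} bottleneck gens"
                )
        else:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class SimulatedLine:
    """Everything simulated for one line (truth plus observables)."""

    line_id: str
    group: str
    acid_level: float
    realized_freqs: np.ndarray
    realized_het: float
    relative_het: float
    reads: pd.DataFrame | None  # None if the line "failed sequencing"
    traits: pd.DataFrame
    viability: pd.DataFrame
    extinction_gen: int | None


def simulate_phenotypes(
    line_id: str,
    relative_het: float,
    params: PhenotypeParams,
    rng: np.random.Generator,
    group: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, int | None]:
    """Trait trajectories, viability counts and extinction for one line.

    Extinction: each generation the simulated adult output is
    Normal(out_base + out_gain * relative_het, out_sd); the first
    generation (1..n_generations - 1) where fewer than 200 adults are
    available marks the line extinct, and trait observation stops at the
    preceding generation.  Generation-10 viability is assayed only for
    survivors.
    """
    p = params
    ngen = p.n_generations
    output = p.out_base + p.out_gain * relative_het + rng.normal(0.0, p.out_sd, size=ngen - 1)
    below = np.nonzero(output < 200.0)[0]
    extinction_gen: int | None = int(below[0]) + 1 if below.size else None
    last_obs = ngen if extinction_gen is None else extinction_gen - 1

    rows = []
    for g in range(1, last_obs + 1):
        prod = p.productivity_baseline + p.productivity_beta * relative_het * g
        prod = max(0.0, prod + rng.normal(0.0, p.productivity_sd))
        rows.append((line_id, group, g, "productivity", prod, 1, np.nan))
        mass_mu = p.body_mass_baseline + p.body_mass_beta * relative_het * g
        males = rng.normal(mass_mu, p.body_mass_ind_sd, size=p.n_males_weighed)
        rows.append(
            (line_id, group, g, "body_mass", float(males.mean()),
             p.n_males_weighed, float(males.std(ddof=1)))
        )
    traits = pd.DataFrame(
        rows, columns=["line_id", "group", "generation", "trait", "value", "n", "sd"]
    )

    v0_stress = float(np.clip(rng.normal(p.stress_v0_mean, p.stress_v0_sd), 0.02, 0.98))
    v0_benign = float(np.clip(rng.normal(p.benign_v0_mean, p.benign_v0_sd), 0.02, 0.99))
    vrows = [
        (line_id, "stress", 0, p.eggs_gen0, int(rng.binomial(p.eggs_gen0, v0_stress))),
        (line_id, "benign", 0, p.eggs_gen0, int(rng.binomial(p.eggs_gen0, v0_benign))),
    ]
    if extinction_gen is None:
        v10_stress = float(np.clip(v0_stress + p.stress_gain * relative_het, 0.0, 0.98))
        v10_benign = float(np.clip(v0_benign - p.benign_cost, 0.0, 1.0))
        vrows.append(
            (line_id, "stress", 10, p.eggs_gen10, int(rng.binomial(p.eggs_gen10, v10_stress)))
        )
        vrows.append(
            (line_id, "benign", 10, p.eggs_gen10, int(rng.binomial(p.eggs_gen10, v10_benign)))
        )
    viability = pd.DataFrame(
        vrows, columns=["line_id", "medium", "generation", "eggs", "survivors"]
    )
    return traits, viability, extinction_gen


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Stated world of the synthetic study.

    Defaults mirror the emulated design: 42/40/40 inbred lines of 2/3/5
    bottleneck generations at census 4 plus 10 outbred controls (132
    lines), 15-male pools, 30,000 founder loci (so post-filter SNP counts
    land in the reported 11,267-35,496 range), per-generation effective
    gene-copy numbers drawn uniformly from {3..14} to emulate realized
    breeder-number and reproductive-success variance, and ~10 % sequencing
    failure (119/132 lines with usable diversity).
    """

    master_seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"Low": 42, "Medium": 40, "High": 40, "OB": 10}
    )
    n_loci: int = 30000
    freq_law: tuple = ("beta", 0.5, 0.5)
    chrom_weights: dict[str, float] | None = None
    n_males: int = 15
    depth_law: tuple = ("nbinom", 3.0, 45.0)
    max_cov: int = 600
    n_flush_gens: int = 2
    effective_copies_range: tuple[int, int] = (3, 14)
    p_seq_fail: float = 0.1
    frac_low_acid: float = 84.0 / 122.0
    phenotypes: PhenotypeParams = field(default_factory=PhenotypeParams)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.p_seq_fail <= 1.0:
            raise ValueError("p_seq_fail must lie in [0, 1]")
        lo, hi = self.effective_copies_range
        if lo < 2 or hi < lo:
            raise ValueError("effective_copies_range must satisfy 2 <= lo <= hi")


@dataclass
class Cohort:
    """A full synthetic study: truth manifest plus observable tables."""

    config: CohortConfig
    pool: FounderPool
    lines: list[SimulatedLine]
    manifest: pd.DataFrame  # line_id, group, design gens, acid, relhet, extinction, seq ok

    @property
    def traits(self) -> pd.DataFrame:
        frames = [l.traits for l in self.lines if len(l.traits)]
        if not frames:  # every line extinct at generation 1
            return self.lines[0].traits
        return pd.concat(frames, ignore_index=True)

    @property
    def viability(self) -> pd.DataFrame:
        return pd.concat([l.viability for l in self.lines], ignore_index=True)

    @property
    def read_tables(self) -> dict[str, pd.DataFrame]:
        return {l.line_id: l.reads for l in self.lines if l.reads is not None}


def _line_rng(master_seed: int, index: int) -> np.random.Generator:
    # reproducible per-line stream keyed on (master seed, line index)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(index)]))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic study, deterministic under the master seed."""
    config = CohortConfig() if config is None else config
    pool = make_founder_pool(
        config.n_loci,
        freq_law=config.freq_law,
        chrom_weights=config.chrom_weights,
        seed=np.random.SeedSequence([int(config.master_seed), 982451653]),
    )
    founder_het = pool.founder_het

    lo, hi = config.effective_copies_range

    lines: list[SimulatedLine] = []
    manifest_rows = []
    index = 0
    for group in ("Low", "Medium", "High", "OB"):
        design = PAPER_DESIGNS.get(group)
        for i in range(config.group_sizes.get(group, 0)):
            rng = _line_rng(config.master_seed, index)
            line_id = f"{group}{i + 1:02d}" if group != "OB" else f"OB{i + 1}"
            if group == "OB":
                acid = 2.5
                copies = [2 * PAPER_DESIGNS["Low"].flush_size] * config.n_flush_gens
            else:
                acid = 1.0 if rng.random() < config.frac_low_acid else 2.5
                steps = design.recursion_steps()
                # realized breeder numbers and reproductive-success skew make
                # the per-generation effective copy number vary widely around
                # the census value 2N = 8
                copies = list(rng.integers(lo, hi + 1, size=steps))
                copies += [2 * design.flush_size] * config.n_flush_gens
            freqs = _drift_chain(pool.p0, copies, rng)
            realized_het = float(np.sum(freqs * (1.0 - freqs)))
            relhet = realized_het / founder_het

            seq_failed = rng.random() < config.p_seq_fail
            reads = None
            if not seq_failed:
                reads = simulate_pool_reads(
                    freqs,
                    loci=pool.loci,
                    n_males=config.n_males,
                    depth_law=config.depth_law,
                    max_cov=config.max_cov,
                    seed=rng,
                )
            traits, viability, ext = simulate_phenotypes(
                line_id, relhet, config.phenotypes, rng, group=group
            )
            lines.append(
                SimulatedLine(
                    line_id=line_id,
                    group=group,
                    acid_level=acid,
                    realized_freqs=freqs,
                    realized_het=realized_het,
                    relative_het=relhet,
                    reads=reads,
                    traits=traits,
                    viability=viability,
                    extinction_gen=ext,
                )
            )
            manifest_rows.append(
                {
                    "line_id": line_id,
                    "group": group,
                    "n_bottleneck_gens": design.n_bottleneck_gens if design else 0,
                    "acid_level": acid,
                    "relative_het": relhet,
                    "extinction_gen": ext if ext is not None else -1,
                    "sequenced": not seq_failed,
                }
            )
            index += 1
    manifest = pd.DataFrame(manifest_rows)
    return Cohort(config=config, pool=pool, lines=lines, manifest=manifest)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write the observable tables (TSV variant tables + CSVs) to disk."""
    outdir = Path(outdir)
    vdir = outdir / "variants"
    vdir.mkdir(parents=True, exist_ok=True)
    for stale in vdir.glob("*.tsv"):  # a reused outdir must not mix cohorts
        stale.unlink()
    paths: dict[str, Path] = {}
    for line_id, table in cohort.read_tables.items():
        p = vdir / f"{line_id}.tsv"
        table.to_csv(p, sep="\t", index=False, float_format="%.6f")
    paths["variants_dir"] = vdir
    for name, df in (
        ("traits", cohort.traits),
        ("viability", cohort.viability),
        ("manifest", cohort.manifest),
    ):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6f")
        paths[name] = p
    return paths
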