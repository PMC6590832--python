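"""End-to-end orchestration: simulate -> diversity -> respond -> compare.

Every stage consumes only files written by earlier stages (or the run
configuration), so each can also be run standalone from the CLI.  Outputs
are stamped with the configuration hash and master seed; re-running with
an identical configuration reproduces identical CSV values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import diversity as div
from . import response as resp
from .pedigree import (
    PAPER_DESIGNS,
    expected_het_retention,
    expected_inbreeding,
    ne_label_transposition_note,
    theory_table,
)
from .simulate import (
    CohortConfig,
    PhenotypeParams,
    generate_cohort,
    make_founder_pool,
    simulate_pair_mating_ibd,
    write_cohort,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_cohort", "validate_against_theory"]

log = logging.getLogger("evopool")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    master_seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    min_cov: int = 10
    max_cov: int = 600
    min_count: int = 1
    min_freq: float = 0.10
    autosomes: tuple[str, ...] = ("2", "3", "4")
    alpha: float = 0.05
    min_lines: int = 10

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(self.cohort)
        if "phenotypes" in kwargs and isinstance(kwargs["phenotypes"], dict):
            kwargs["phenotypes"] = PhenotypeParams(**kwargs["phenotypes"])
        return CohortConfig(master_seed=self.master_seed, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "autosomes" in data:
            data["autosomes"] = tuple(str(c) for c in data["autosomes"])
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(outdir: Path, config: RunConfig) -> None:
    (outdir / "run_stamp.json").write_text(
        json.dumps({"config_hash": config.digest(), "master_seed": config.master_seed})
    )


def analyze_cohort(cohort, config: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """In-memory diversity -> respond -> compare over a generated cohort.

    Same computations as :func:`run_pipeline` without the file round-trip;
    useful for replicate studies.  Returns the diversity, slopes,
    viability-change, comparison and contrast tables.
    """
    config = RunConfig() if config is None else config
    manifest = cohort.manifest
    outbred_ids = manifest.loc[manifest["group"] == "OB", "line_id"].tolist()
    diversity = div.diversity_table(
        cohort.read_tables,
        outbred_ids=outbred_ids,
        min_cov=config.min_cov,
        max_cov=config.max_cov,
        min_count=config.min_count,
        min_freq=config.min_freq,
        autosomes=config.autosomes,
    )
    not_extinct = manifest.loc[
        manifest["extinction_gen"].fillna(-1).astype(float) < 0, "line_id"
    ]
    eligible_ids = set(not_extinct) & set(diversity["line_id"])
    slopes = resp.slopes_table(cohort.traits, eligible_ids=eligible_ids)
    vchanges = resp.viability_change_table(
        cohort.viability[cohort.viability["line_id"].isin(eligible_ids)]
    )
    report = cmp.compare_predictors(
        slopes, vchanges, diversity, manifest, alpha=config.alpha,
        min_lines=config.min_lines,
    )
    return {
        "diversity": diversity,
        "slopes": slopes,
        "viability_changes": vchanges,
        "comparison": report["comparison"],
        "contrasts": report["contrasts"],
        "eligible": report["eligible"],
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Execute all stages in order; returns the key result tables.

    Writes: variants/, traits.csv, viability.csv, manifest.csv,
    diversity.csv, ks_diagnostic.csv, slopes.csv, viability_changes.csv,
    comparison_report.csv, group_contrasts.csv, theory_check.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _stamp(outdir, config)

    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort_config())
        write_cohort(cohort, outdir)
        log.info("simulate: %d lines, %d founder loci", len(cohort.lines), len(cohort.pool))

        stage = "diversity"
        vdir = outdir / "variants"
        tables = {p.stem: div.read_variant_tsv(p) for p in sorted(vdir.glob("*.tsv"))}
        if not tables:
            raise ValueError("no variant tables were produced")
        manifest = pd.read_csv(outdir / "manifest.csv")
        outbred_ids = manifest.loc[manifest["group"] == "OB", "line_id"].tolist()
        diversity = div.diversity_table(
            tables,
            outbred_ids=outbred_ids,
            min_cov=config.min_cov,
            max_cov=config.max_cov,
            min_count=config.min_count,
            min_freq=config.min_freq,
            autosomes=config.autosomes,
        )
        diversity.to_csv(outdir / "diversity.csv", index=False, float_format="%.6f")
        group_of = manifest.set_index("line_id")["group"]
        cov_by_group: dict[str, np.ndarray] = {}
        for lid, t in tables.items():
            g = group_of.get(lid)
            if g is not None:
                cov_by_group.setdefault(g, []).append(t["coverage"].to_numpy())
        ks = div.coverage_ks_diagnostic(
            {g: np.concatenate(v) for g, v in cov_by_group.items()}, alpha=config.alpha
        )
        ks.to_csv(outdir / "ks_diagnostic.csv", index=False, float_format="%.6f")
        log.info("diversity: %d lines with pi, %d K-S pairs", len(diversity), len(ks))

        stage = "respond"
        traits = pd.read_csv(outdir / "traits.csv")
        viability = pd.read_csv(outdir / "viability.csv")
        not_extinct = manifest.loc[
            manifest["extinction_gen"].fillna(-1).astype(float) < 0, "line_id"
        ]
        eligible_ids = set(not_extinct) & set(diversity["line_id"])
        slopes = resp.slopes_table(traits, eligible_ids=eligible_ids)
        slopes.to_csv(outdir / "slopes.csv", index=False, float_format="%.6f")
        vchanges = resp.viability_change_table(
            viability[viability["line_id"].isin(eligible_ids)]
        )
        vchanges.to_csv(outdir / "viability_changes.csv", index=False, float_format="%.6f")
        log.info(
            "respond: %d eligible lines (of %d), %d slope rows",
            len(eligible_ids), len(manifest), len(slopes),
        )

        stage = "compare"
        report = cmp.compare_predictors(
            slopes, vchanges, diversity, manifest,
            alpha=config.alpha, min_lines=config.min_lines,
        )
        report["comparison"].to_csv(
            outdir / "comparison_report.csv", index=False, float_format="%.6f"
        )
        report["contrasts"].to_csv(
            outdir / "group_contrasts.csv", index=False, float_format="%.6f"
        )

        stage = "theory"
        check = validate_against_theory(seed=config.master_seed)
        check["table"].to_csv(outdir / "theory_check.csv", index=False, float_format="%.6f")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    return {
        "diversity": diversity,
        "slopes": slopes,
        "viability_changes": vchanges,
        "comparison": report["comparison"],
        "contrasts": report["contrasts"],
        "theory_check": check["table"],
    }


def validate_against_theory(
    seed: int = 0,
    n_replicates: int = 1000,
    n_loci: int = 200,
    ibd_replicates: int = 100_000,
    n_flush_gens: int = 0,
) -> dict:
    """Theory table plus the simulator's calibration against its oracles.

    For each bottleneck design: (a) mean retained frequency-level
    heterozygosity over ``n_replicates`` binomial-drift lines against
    (1 - 1/(2 Ne))^t; (b) mean within-individual autozygosity of the
    genealogical pair-mating simulator against the two-generation F
    recursion.  A calibration falling outside 3 Monte-Carlo SEs of its
    oracle is flagged as failed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    pool = make_founder_pool(
        n_loci, seed=np.random.SeedSequence([int(seed), 11])
    )
    rows = []
    for name, design in PAPER_DESIGNS.items():
        steps = design.recursion_steps()
        # (a) binomial drift vs het-retention oracle
        p = np.broadcast_to(pool.p0, (n_replicates, n_loci)).copy()
        census = [design.bottleneck_size] * steps + [design.flush_size] * n_flush_gens
        for n in census:
            p = rng.binomial(2 * n, p) / (2.0 * n)
        h0 = np.sum(pool.p0 * (1 - pool.p0))
        retention = np.sum(p * (1 - p), axis=1) / h0
        exp_ret = expected_het_retention(design.bottleneck_size, steps)
        for n in [design.flush_size] * n_flush_gens:
            exp_ret *= expected_het_retention(n, 1)
        se_ret = retention.std(ddof=1) / np.sqrt(n_replicates)
        # (b) genealogical pair mating vs the F recursion
        exp_f = expected_inbreeding(design.bottleneck_size, steps).final
        auto = simulate_pair_mating_ibd(
            steps, ibd_replicates, n_adults=design.bottleneck_size,
            seed=np.random.SeedSequence([int(seed), 13, steps]),
            return_replicates=True,
        )
        realized_f = float(auto.mean())
        se_f = float(auto.std(ddof=1) / np.sqrt(ibd_replicates)) if steps else 1e-12
        rows.append(
            {
                "design": name,
                "recursion_steps": steps,
                "expected_retention": exp_ret,
                "realized_retention": float(retention.mean()),
                "retention_mc_se": float(se_ret),
                "retention_ok": bool(abs(retention.mean() - exp_ret) <= 3 * se_ret),
                "expected_f": exp_f,
                "realized_f_ibd": realized_f,
                "f_mc_se": float(se_f),
                "f_ok": bool(abs(realized_f - exp_f) <= 3 * se_f),
            }
        )
    table = pd.DataFrame(rows)
    ok = bool(table["retention_ok"].all() and table["f_ok"].all())
    return {
        "table": theory_table().merge(
            table, on=["design", "recursion_steps"], suffixes=("", "_sim")
        ),
        "calibration": table,
        "ok": ok,
        "note": ne_label_transposition_note(),
    }
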