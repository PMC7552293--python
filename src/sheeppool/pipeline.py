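"""End-to-end workflow: pilot MAF -> pooled-screen design -> simulated screen
-> per-breed locus parameters -> pairwise LD -> genotype-trait association.

A run is a pure function of (config, seed): stage seeds are spawned
deterministically from the global seed, outputs carry the seed, package
version and a config hash, and the structured log is timestamp-free, so the
same config and seed reproduce every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_table
from .io import write_genotype_csv
from .ld import em_haplotypes
from .pool_design import design_curve, estimate_pilot_maf, savings_report
from .pool_sim import make_pools, screen
from .popgen import breed_table
from .synthetic_data import (
    PopulationSpec,
    TwoLocusSpec,
    generate_population,
    generate_traits,
    generate_two_locus,
    tan_sheep_population_spec,
    tan_sheep_trait_specs,
)

__all__ = ["demo_config", "load_config", "validate_config", "run_pipeline"]


def demo_config(seed: int = 1) -> dict:
    """Bundled demo: the seven-breed cohort, design at the pilot-rounded MAF 0.01,
    three weak-LD locus pairs, and the Tan-sheep trait panel."""
    return {
        "seed": seed,
        "out_dir": "runs/demo",
        "pilot": {"n": 50},
        "design": {"maf": 0.01, "a_min": 3, "a_max": 20},
        "ld_pairs": [
            {"name": "chchd7del8__plag1del30", "p_a": 0.007, "p_b": 0.05,
             "d_prime": 0.3, "n": 276},
            {"name": "chchd7del8__plag1del45", "p_a": 0.007, "p_b": 0.04,
             "d_prime": 0.3, "n": 276},
            {"name": "plag1del30__plag1del45", "p_a": 0.05, "p_b": 0.04,
             "d_prime": 0.3, "n": 276},
        ],
        "association": {"breed": "TS", "noise_family": "skewed"},
        "log_level": "info",
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check before any stage runs."""
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in cfg or int(cfg["seed"]) != cfg["seed"]:
        raise ValueError("config needs an integer 'seed'")
    design = cfg.get("design", {})
    if "maf" in design and not 0.0 <= design["maf"] <= 1.0:
        raise ValueError("design.maf must lie in [0, 1]")
    for key in ("a_min", "a_max"):
        if key in design and design[key] < 1:
            raise ValueError(f"design.{key} must be >= 1")
    for pair in cfg.get("ld_pairs", []):
        for f in ("p_a", "p_b", "d_prime", "n"):
            if f not in pair:
                raise ValueError(f"ld_pairs entry missing field {f!r}")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Log:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.records: list[dict] = []

    def stage(self, name: str, **info) -> None:
        rec = {"stage": name, **info}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def run_pipeline(config: dict, out_dir=None) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage name while earlier outputs are
    kept on disk.
    """
    validate_config(config)
    seed = int(config["seed"])
    run_dir = Path(out_dir or config.get("out_dir", "runs/run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _Log(run_dir / "log.jsonl")
    log.path.write_text("")
    meta = {
        "seed": seed,
        "version": __version__,
        "config_hash": _config_hash(config),
    }
    (run_dir / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    stage_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(6)]

    current = "population"
    try:
        pop_spec = tan_sheep_population_spec(seed=stage_seeds[0])
        population = generate_population(pop_spec)
        write_genotype_csv(population, run_dir / "genotypes.csv")
        log.stage(current, n=len(population), **meta)

        current = "pilot"
        n_pilot = int(config.get("pilot", {}).get("n", 50))
        rng = np.random.default_rng(stage_seeds[1])
        pilot_idx = rng.choice(len(population), size=n_pilot, replace=False)
        pilot_geno = population["genotype"].to_numpy()[pilot_idx]
        pilot = estimate_pilot_maf(
            (int((pilot_geno == 0).sum()), int((pilot_geno == 1).sum()),
             int((pilot_geno == 2).sum()))
        )
        (run_dir / "pilot.json").write_text(
            json.dumps(
                {"n_pilot": pilot.n_pilot, "counts": pilot.counts,
                 "maf_hat": pilot.maf_hat},
                indent=2,
            ) + "\n"
        )
        log.stage(current, maf_hat=pilot.maf_hat)

        current = "design"
        dcfg = config.get("design", {})
        maf = float(dcfg.get("maf", pilot.maf_hat))
        curve = design_curve(
            len(population), maf, int(dcfg.get("a_min", 3)), int(dcfg.get("a_max", 20))
        )
        curve.to_frame().to_csv(run_dir / "curve.tsv", sep="\t", index=False)
        log.stage(current, **savings_report(curve))

        current = "screen"
        plan = make_pools(population["id"].tolist(), curve.optimum.a, stage_seeds[2])
        outcome = screen(population, plan)
        (run_dir / "outcome.json").write_text(
            json.dumps(
                {
                    "a": plan.a,
                    "pool_tests": outcome.pool_tests,
                    "retests": outcome.retests,
                    "total_reactions": outcome.total_reactions,
                    "pools": [list(g) for g in plan.assignments],
                },
                indent=2,
            ) + "\n"
        )
        log.stage(current, total_reactions=outcome.total_reactions)

        current = "popgen"
        table1 = breed_table(population)
        table1.to_csv(run_dir / "table1.tsv", sep="\t", index=False)
        log.stage(current, breeds=len(table1))

        current = "ld"
        rows = []
        for i, pair in enumerate(config.get("ld_pairs", [])):
            spec = TwoLocusSpec(
                p_a=pair["p_a"], p_b=pair["p_b"], d_prime=pair["d_prime"],
                n=int(pair["n"]), seed=stage_seeds[3] + i,
            )
            data = generate_two_locus(spec)
            try:
                res = em_haplotypes(data["locus1"], data["locus2"])
                rows.append(
                    {"pair": pair["name"], "n": spec.n, "D": res.d,
                     "Dprime": res.d_prime, "r2": res.r2,
                     "strength": res.strength, "iterations": res.iterations}
                )
            except ValueError as exc:  # a rare allele may be absent at this n
                rows.append(
                    {"pair": pair["name"], "n": spec.n, "D": float("nan"),
                     "Dprime": float("nan"), "r2": float("nan"),
                     "strength": f"undefined ({exc})", "iterations": 0}
                )
        pd.DataFrame(rows).to_csv(run_dir / "ld.tsv", sep="\t", index=False)
        log.stage(current, pairs=len(rows))

        current = "association"
        acfg = config.get("association", {})
        breed = acfg.get("breed", "TS")
        subset = population[population["breed"] == breed]
        traits = generate_traits(
            subset,
            tan_sheep_trait_specs(acfg.get("noise_family", "skewed")),
            seed=stage_seeds[4],
        )
        traits.to_csv(run_dir / "traits.csv", index=False)
        table2 = association_table(traits, stratify_by_sex=True)
        table2.to_csv(run_dir / "table2.tsv", sep="\t", index=False)
        n_sig = int(table2.get("significant", pd.Series(dtype=bool)).sum())
        log.stage(current, rows=len(table2), significant=n_sig)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    return run_dir
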