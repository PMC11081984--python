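"""End-to-end pipeline: simulate -> LCQ hotspots -> grade -> neighbours -> report.

Every stochastic stage carries an explicit seed which is resolved before any
computation and recorded in the output directory, so re-running from the
written run config reproduces every output byte-for-byte (timings live only
in the human-readable log).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .alveolar_stats import (
    compare_dimensions,
    compare_neighbour_positivity,
    grade_alveoli,
    grade_distribution,
    neighbour_table,
    sample_alveoli,
)
from .errors import ComputationError, ConfigError, PipelineError
from .io import (
    sim_config_from_dict,
    sim_config_to_dict,
    write_lcq_results,
    write_simulation,
)
from .lcq_core import hotspot_map, knn_bandwidths, permutation_test
from .synthetic_tissue import SimConfig, simulate_tissue

__all__ = ["RunConfig", "run_pipeline"]

SCHEMA_VERSION = "1"

# Fixed offsets used to resolve per-stage seeds from the simulation seed when
# the user does not set them explicitly; kept below 2^31 after resolution.
_PERM_SEED_OFFSET = 1_000_003
_SAMPLE_SEED_OFFSET = 2_000_003


@dataclass(frozen=True)
class RunConfig:
    """Parameters for the full pipeline; unknown keys in files are rejected."""

    sim: SimConfig
    k: int = 10
    n_perm: int = 999
    alpha: float = 0.05
    truncation_radius: Optional[float] = 4.0
    perm_seed: Optional[int] = None
    sample_seed: Optional[int] = None
    n_seed_alveoli: int = 25
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> None:
        self.sim.validate()
        if self.k < 1:
            raise ConfigError(f"k must be >= 1, got {self.k}")
        if self.n_perm < 99:
            raise ConfigError(f"n_perm must be >= 99, got {self.n_perm}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.truncation_radius is not None and self.truncation_radius <= 0:
            raise ConfigError("truncation_radius must be positive or null")
        if self.n_seed_alveoli < 1:
            raise ConfigError("n_seed_alveoli must be >= 1")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version!r}; "
                f"this build reads {SCHEMA_VERSION!r}"
            )

    def resolved(self) -> "RunConfig":
        """Fill in derived per-stage seeds (kept below 2^31)."""
        perm = self.perm_seed
        samp = self.sample_seed
        if perm is None:
            perm = (self.sim.seed + _PERM_SEED_OFFSET) % (2**31)
        if samp is None:
            samp = (self.sim.seed + _SAMPLE_SEED_OFFSET) % (2**31)
        return dataclasses.replace(self, perm_seed=perm, sample_seed=samp)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = sim_config_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("run config must be a mapping")
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ConfigError(f"unknown run-config keys: {sorted(unknown)}")
        if "sim" not in d:
            raise ConfigError("run config requires a 'sim' section")
        sim = sim_config_from_dict(d["sim"])
        kwargs = {k: v for k, v in d.items() if k != "sim"}
        cfg = cls(sim=sim, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(Path(path), encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _comparison_dict(gc) -> dict:
    return {
        "test": gc.test_name,
        "statistic": float(gc.statistic),
        "p_value": float(gc.p_value),
        "group_sizes": list(gc.group_sizes),
        "group_means": [float(m) for m in gc.group_means],
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    A failure inside the LCQ stage (e.g. too few positive cells) is recorded
    in the summary and the remaining alveolar stages still run; a failure in
    any other stage aborts with the stage name and the propagated cause.
    """
    config.validate()
    config = config.resolved()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    import networkx, numpy, pandas, scipy  # versions for the audit log

    log(f"lcqspatial {__version__} (schema {config.schema_version})")
    log(
        "versions: numpy %s scipy %s pandas %s networkx %s"
        % (numpy.__version__, scipy.__version__, pandas.__version__, networkx.__version__)
    )
    log(
        f"seeds: sim={config.sim.seed} perm={config.perm_seed} sample={config.sample_seed}"
    )

    with open(out_dir / "run_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    summary: dict = {"schema_version": config.schema_version}
    stages_completed: list[str] = []
    stages_failed: dict[str, str] = {}
    timings: dict[str, float] = {}

    def run_stage(name: str, fn, isolate: bool = False):
        t0 = time.perf_counter()
        try:
            result = fn()
        except ComputationError as exc:
            if isolate:
                stages_failed[name] = str(exc)
                log(f"stage {name}: FAILED ({exc}); continuing")
                return None
            raise PipelineError(name, exc) from exc
        except (ConfigError, OSError) as exc:
            raise PipelineError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        stages_completed.append(name)
        log(f"stage {name}: ok ({timings[name]:.2f} s)")
        return result

    def write_summary_and_log() -> None:
        summary["stages_completed"] = stages_completed
        summary["stages_failed"] = stages_failed
        summary["partial"] = bool(stages_failed)
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, sort_keys=True, indent=2)
            fh.write("\n")
        for name, t in timings.items():
            log(f"timing {name}: {t:.3f} s")
        with open(out_dir / "log.txt", "w", encoding="utf-8") as fh:
            fh.write("\n".join(log_lines) + "\n")

    # -- simulate
    def _simulate():
        return simulate_tissue(config.sim)

    try:
        pattern, alveoli, adjacency, mask = run_stage("simulate", _simulate)
        write_simulation(pattern, alveoli, adjacency, mask, out_dir, config=config.sim)
        summary["n_cells"] = pattern.n_cells
        summary["n_positive"] = pattern.n_positive
        summary["void_pixels"] = mask.void_pixel_count
        log(
            f"N_A={pattern.n_cells} N_B={pattern.n_positive} "
            f"void_pixels={mask.void_pixel_count}"
        )

        # -- LCQ hotspots (isolated: alveolar stages survive an undefined quotient)
        def _lcq():
            bw = knn_bandwidths(pattern, k=config.k)
            res = permutation_test(
                pattern,
                bw,
                n_perm=config.n_perm,
                seed=config.perm_seed,
                alpha=config.alpha,
                truncation_radius=config.truncation_radius,
            )
            write_lcq_results(res, pattern, out_dir / "lcq_results.csv")
            with open(out_dir / "lcq_meta.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(
                    {k: (v.item() if hasattr(v, "item") else v)
                     for k, v in res.meta.items()},
                    fh,
                    sort_keys=True,
                )
            hotspot_map(pattern, res, mask, out_dir / "hotspot_map.png")
            n_sig = int(res.significant.sum())
            return {
                "n_significant": n_sig,
                "fraction_significant": n_sig / pattern.n_cells,
                "k": config.k,
                "n_perm": config.n_perm,
                "alpha": config.alpha,
                "seed": config.perm_seed,
            }

        lcq_summary = run_stage("lcq", _lcq, isolate=True)
        summary["lcq"] = (
            lcq_summary if lcq_summary is not None
            else {"error": stages_failed.get("lcq")}
        )

        # -- grading
        def _grade():
            grades = grade_alveoli(pattern, alveoli)
            dist = grade_distribution(grades)
            with open(out_dir / "graded_alveoli.csv", "w", encoding="utf-8") as fh:
                fh.write("alveolus_id,n_epithelial,n_positive,fraction,grade,any_positive\n")
                for g in grades:
                    fh.write(
                        f"{g.alveolus_id},{g.n_epithelial},{g.n_positive},"
                        f"{g.fraction_positive:.6g},{g.grade},"
                        f"{'true' if g.any_positive else 'false'}\n"
                    )
            return grades, dist

        grades, dist = run_stage("grade", _grade)
        summary["grades"] = {
            "histogram": list(dist.counts),
            "extremity_fraction": dist.extremity_fraction,
            "n_alveoli": dist.n,
        }

        # -- neighbour analysis
        def _neighbours():
            pos_sample, neg_sample = sample_alveoli(
                grades, config.n_seed_alveoli, seed=config.sample_seed
            )
            pos_stats = neighbour_table(pos_sample, adjacency, grades)
            neg_stats = neighbour_table(neg_sample, adjacency, grades)
            with open(out_dir / "neighbour_stats.csv", "w", encoding="utf-8") as fh:
                fh.write(
                    "seed_alveolus_id,seed_stratum,n_neighbours,"
                    "n_positive_neighbours,pct_positive_neighbours\n"
                )
                for stratum, stats in (("positive", pos_stats), ("negative", neg_stats)):
                    for s in stats:
                        fh.write(
                            f"{s.seed_alveolus_id},{stratum},{s.n_neighbours},"
                            f"{s.n_positive_neighbours},{s.pct_positive_neighbours:.6g}\n"
                        )
            gc = compare_neighbour_positivity(pos_stats, neg_stats)
            out = _comparison_dict(gc)
            out["n_isolated_excluded"] = (
                len(pos_sample) + len(neg_sample) - len(pos_stats) - len(neg_stats)
            )
            out["seed"] = config.sample_seed
            return out

        summary["neighbours"] = run_stage("neighbours", _neighbours)

        # -- dimension null
        def _dimensions():
            by_id = {a.id: a for a in alveoli}
            pos = [by_id[g.alveolus_id] for g in grades if g.any_positive]
            neg = [by_id[g.alveolus_id] for g in grades if not g.any_positive]
            comps = compare_dimensions(pos, neg)
            return {dim: _comparison_dict(gc) for dim, gc in comps.items()}

        summary["dimensions"] = run_stage("dimensions", _dimensions)
    except PipelineError as exc:
        stages_failed[exc.stage] = str(exc.cause)
        log(f"stage {exc.stage}: ABORTED ({exc.cause})")
        write_summary_and_log()
        raise

    write_summary_and_log()
    return summary
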