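"""End-to-end orchestration: simulate -> preprocess -> annotate -> diffexpr (-> qpcr).

A run is driven by a TOML config and a seed, writes every stage's outputs into
one directory, and records a manifest (config snapshot, seed, SHA-256 digest
per output, stage timings, package version) so that identical (config, seed)
runs are byte-identical and individually re-checkable.
"""

from __future__ import annotations

import hashlib
import json
import time
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import arm_report, category_proportions, quantify_mirnas
from .diffexpr import call_de, de_report
from .io import (
    CountTable,
    write_count_table,
    write_ct_table,
    write_reference_bundle,
    write_tag_table,
)
from .preprocess import clean_and_collapse, length_distribution
from .qpcr import anova_oneway, ddct, duncan_mrt
from .simulate import (
    SimulationConfig,
    build_reference,
    simulate_counts,
    simulate_ct_table,
    simulate_reads,
    simulate_truth,
)

__all__ = ["PipelineConfig", "RunManifest", "load_config", "run_pipeline", "recovery_report"]


@dataclass
class PipelineConfig:
    """All thresholds of a run, with the original study's analysis defaults:
    18-30 nt window, alpha 0.05, |log2 ratio| >= 1, immature library as control."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quality_floor: float = 20.0
    min_len: int = 18
    max_len: int = 30
    min_overlap: int = 6
    keep_singletons: bool = False
    alpha: float = 0.05
    lfc_min: float = 1.0
    control: str | None = None
    qpcr: dict | None = None  # {"groups": [...], "levels": {...}, "replicates", "noise_sd", "calibrator"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("need 0 < min_len <= max_len")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML run config; unknown keys are a hard error before any stage runs."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_kwargs = raw.pop("simulation", {})
    for tup in ("library_sizes", "library_names"):
        if tup in sim_kwargs:
            sim_kwargs[tup] = tuple(sim_kwargs[tup])
    if "length_law" in sim_kwargs:
        sim_kwargs["length_law"] = {int(k): float(v) for k, v in sim_kwargs["length_law"].items()}
    known = set(PipelineConfig.__dataclass_fields__) - {"simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim_known = set(SimulationConfig.__dataclass_fields__)
    sim_unknown = set(sim_kwargs) - sim_known
    if sim_unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(sim_unknown)}")
    return PipelineConfig(simulation=SimulationConfig(**sim_kwargs), **raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def recovery_report(de: pd.DataFrame, truth: pd.DataFrame, ne_floor: float = 50.0) -> dict:
    """Compare DE calls against simulator ground truth.

    Sensitivity is reported both over all planted miRNAs and restricted to
    those with base normalized expression >= ``ne_floor``, where the
    two-library exact test has power; direction accuracy is over significant
    true positives.
    """
    base_ne = truth["base_ne"]
    planted = truth.index[truth["true_log2fc"] != 0.0]
    called = de.index[de["direction"] != "equal"] if len(de) else pd.Index([])
    tp = planted.intersection(called)
    expressed = planted[base_ne.loc[planted] >= ne_floor]
    tp_expressed = expressed.intersection(called)
    correct_dir = sum(
        1
        for m in tp
        if (de.loc[m, "direction"] == "up") == (truth.loc[m, "true_log2fc"] > 0)
    )
    null = truth.index[truth["true_log2fc"] == 0.0]
    fp = null.intersection(called)
    return {
        "n_planted": int(len(planted)),
        "n_called": int(len(called)),
        "sensitivity_all": float(len(tp) / len(planted)) if len(planted) else float("nan"),
        "sensitivity_expressed": (
            float(len(tp_expressed) / len(expressed)) if len(expressed) else float("nan")
        ),
        "direction_accuracy": float(correct_dir / len(tp)) if len(tp) else float("nan"),
        "false_positives_among_null_mirnas": int(len(fp)),
    }


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path, log=print) -> Path:
    """Execute all stages into ``out_dir`` and write ``manifest.json``.

    Read-conservation numbers are logged at each stage; any stage failure
    halts the run with the stage name.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest = RunManifest(
        config={**asdict(config), "simulation": sim.to_dict()},
        seed=sim.seed,
        version=__version__,
    )

    def _stage(name: str):
        t0 = time.perf_counter()

        def done(*paths: Path):
            manifest.timings[name] = round(time.perf_counter() - t0, 3)
            for p in paths:
                manifest.digests[str(p.relative_to(out))] = _sha256(p)

        return done

    # -- simulate ----------------------------------------------------------
    done = _stage("simulate")
    bundle = build_reference(sim)
    truth = simulate_truth(sim)
    counts = simulate_counts(sim, truth)
    ref_dir = out / "reference"
    write_reference_bundle(bundle, ref_dir)
    truth_path = out / "truth.tsv"
    truth.per_mirna.to_csv(truth_path, sep="\t")
    counts_path = out / "simulated_counts.tsv"
    write_count_table(counts, counts_path)
    fastqs = simulate_reads(sim, bundle, counts, out / "reads")
    done(truth_path, counts_path, *fastqs.values(), *sorted(ref_dir.iterdir()))
    log(f"[simulate] {sim.n_mirnas} miRNAs, libraries {dict(counts.totals)}")

    # -- preprocess --------------------------------------------------------
    done = _stage("preprocess")
    libs = {}
    tag_paths = []
    for lib_name, fq in fastqs.items():
        lib = clean_and_collapse(
            fq,
            adapter=sim.adapter,
            quality_floor=config.quality_floor,
            min_len=config.min_len,
            max_len=config.max_len,
            min_overlap=config.min_overlap,
            keep_singletons=config.keep_singletons,
            name=lib_name,
        )
        libs[lib_name] = lib
        p = out / f"tags_{lib_name}.tsv"
        write_tag_table(lib.tags, p)
        tag_paths.append(p)
        ld = length_distribution(lib)
        ldp = out / f"length_distribution_{lib_name}.tsv"
        ld.to_csv(ldp, sep="\t", index=False)
        tag_paths.append(ldp)
        log(
            f"[preprocess] {lib_name}: raw {lib.raw_total} = clean {lib.clean_total}"
            f" + rejects {dict(lib.rejects)}"
        )
    done(*tag_paths)

    # -- annotate ----------------------------------------------------------
    done = _stage("annotate")
    lib_names = list(libs)
    result = quantify_mirnas(libs[lib_names[0]], libs[lib_names[1]], bundle)
    cat_path = out / "category_summary.tsv"
    props = category_proportions(result)
    summary = pd.concat([result.category_totals, props.add_suffix("_pct", axis=1)], axis=1)
    summary.to_csv(cat_path, sep="\t")
    mirna_path = out / "mirna_counts.tsv"
    write_count_table(result.mirna_counts, mirna_path)
    arms = arm_report(result)
    arm_path = out / "arm_report.tsv"
    arms.pairs.to_csv(arm_path, sep="\t")
    done(cat_path, mirna_path, arm_path)
    for lib_name in lib_names:
        assert int(result.category_totals[lib_name].sum()) == libs[lib_name].clean_total
        log(
            f"[annotate] {lib_name}: categories sum {int(result.category_totals[lib_name].sum())}"
            f" == clean {libs[lib_name].clean_total}"
        )

    # -- diffexpr ----------------------------------------------------------
    done = _stage("diffexpr")
    control = config.control or sim.library_names[0]
    de = call_de(result.mirna_counts, control=control, alpha=config.alpha, lfc_min=config.lfc_min)
    de_path = out / "de_results.tsv"
    de.to_csv(de_path, sep="\t")
    rep = de_report(de)
    recovery = recovery_report(de, truth.per_mirna)
    report_path = out / "de_summary.json"
    report_path.write_text(
        json.dumps(
            {
                "n_up": rep.n_up,
                "n_down": rep.n_down,
                "n_equal": rep.n_equal,
                "max_fold_up": rep.max_fold_up,
                "max_fold_down": rep.max_fold_down,
                "recovery": recovery,
            },
            indent=2,
        )
        + "\n"
    )
    done(de_path, report_path)
    log(f"[diffexpr] up {rep.n_up}, down {rep.n_down}, equal {rep.n_equal}; recovery {recovery}")

    # -- qpcr (optional) ---------------------------------------------------
    if config.qpcr:
        done = _stage("qpcr")
        q = config.qpcr
        ct = simulate_ct_table(
            groups=list(q["groups"]),
            true_relative_expression={k: float(v) for k, v in q["levels"].items()},
            replicates=int(q.get("replicates", 3)),
            noise_sd=float(q.get("noise_sd", 0.2)),
            seed=sim.seed,
        )
        ct_path = out / "ct_table.tsv"
        write_ct_table(ct, ct_path)
        rel = ddct(ct, calibrator=q.get("calibrator", list(q["groups"])[0]))
        f_stat, p = anova_oneway(rel)
        res = duncan_mrt(rel, alpha=config.alpha)
        res["letters_0.01"] = duncan_mrt(rel, alpha=0.01)["letters_0.01"]
        q_path = out / "qpcr_results.tsv"
        res.to_csv(q_path, sep="\t")
        (out / "qpcr_anova.json").write_text(
            json.dumps({"F": f_stat, "p_value": p}, indent=2) + "\n"
        )
        done(ct_path, q_path, out / "qpcr_anova.json")
        log(f"[qpcr] ANOVA F={f_stat:.3f} p={p:.4g}")

    manifest.write(out / "manifest.json")
    return out
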