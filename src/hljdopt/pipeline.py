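"""End-to-end orchestration: simulate -> preprocess -> model -> screen -> network.

A run is driven by a :class:`RunConfig` (YAML on disk, strict keys) and a
master seed; every stage derives its own sub-seed as a stable hash of
(master seed, stage name), so adding a stage never perturbs the randomness
of earlier ones.  Each stage writes its artifacts under the run directory
and appends a provenance record (parameters, seed, output SHA-256 hashes,
duration) to ``provenance.json`` plus a line-oriented ``run.log``; re-running
with the same config and seed reproduces identical output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import chemometrics, network, preprocess, univariate
from .simulate import STUDY_GROUPS, StudyConfig, _stage_seed, simulate_study


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults = the study's printed settings)."""

    out_dir: str = "run"
    # simulation
    n_per_group: int = 10
    groups: tuple = STUDY_GROUPS
    effect: float = 1.0
    noise_sd: float = 0.3
    block_r: float = 0.7
    ppm_step: float = 0.001
    spectral_noise_sd: float = 0.002
    global_shift_sd: float = 0.0
    # preprocessing
    bucket_width: float = 0.015
    ppm_min: float = 0.2
    ppm_max: float = 10.0
    exclusions: tuple = ((4.65, 5.25),)
    align: bool = False
    max_shift: float = 0.02
    segment: float = 0.06
    # modeling
    n_orth: int = 1
    folds: int = 2
    cv_repeats: int = 20
    n_permutations: int = 2000
    permutation_cv_repeats: int = 5
    # screening / networks
    alpha: float = 0.05
    r_threshold: float = 0.3
    p_threshold: float = 0.05
    similarity_threshold: float = 0.6
    # reproducibility
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return _stage_seed(self.seed, stage)


_VALIDATORS = {
    "n_per_group": lambda v: v >= 2 or "n_per_group must be >= 2",
    "bucket_width": lambda v: v > 0 or "bucket_width must be > 0",
    "ppm_step": lambda v: v > 0 or "ppm_step must be > 0",
    "noise_sd": lambda v: v >= 0 or "noise_sd must be >= 0",
    "spectral_noise_sd": lambda v: v >= 0 or "spectral_noise_sd must be >= 0",
    "n_permutations": lambda v: v >= 1 or "n_permutations must be >= 1",
    "folds": lambda v: v >= 2 or "folds must be >= 2",
    "cv_repeats": lambda v: v >= 1 or "cv_repeats must be >= 1",
    "n_orth": lambda v: v >= 0 or "n_orth must be >= 0",
    "alpha": lambda v: 0 < v < 1 or "alpha must lie in (0, 1)",
    "r_threshold": lambda v: 0 < v < 1 or "r_threshold must lie in (0, 1)",
    "p_threshold": lambda v: 0 < v < 1 or "p_threshold must lie in (0, 1)",
}


def validate_config(source) -> RunConfig:
    """Load and validate a config file (or dict); collect ALL errors.

    An empty file yields the full default configuration.  Unknown keys are
    rejected (typo safety).  Raises :class:`ConfigError` carrying every
    problem found, not just the first.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"config root must be a mapping, got {type(raw).__name__}"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg_kwargs = {}
    for k, v in raw.items():
        if k not in known:
            continue
        if k in ("groups",):
            v = tuple(v)
        if k == "exclusions":
            v = tuple(tuple(x) for x in v)
        cfg_kwargs[k] = v
    for k, check in _VALIDATORS.items():
        if k in cfg_kwargs:
            res = check(cfg_kwargs[k])
            if res is not True:
                errors.append(str(res))
    if errors:
        raise ConfigError(errors)
    return RunConfig(**cfg_kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Provenance:
    def __init__(self, out: Path):
        self.out = out
        self.records = []
        self.log = open(out / "run.log", "w")

    def note(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.log.write(f"{stamp} {msg}\n")
        self.log.flush()

    def record(self, stage: str, params: dict, seed, outputs: list[Path], t0: float):
        self.records.append(
            {
                "stage": stage,
                "parameters": params,
                "seed": seed,
                "outputs": {str(p.relative_to(self.out)): _sha256(p) for p in outputs},
                "duration_s": round(time.time() - t0, 3),
            }
        )
        (self.out / "provenance.json").write_text(json.dumps(self.records, indent=1))

    def close(self):
        self.log.close()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON).

    Contrasts are every non-model group versus the model group M
    (NC vs M and F1..F9 vs M with the default groups).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _Provenance(out)
    try:
        summary = {"contrasts": {}, "seed": config.seed}

        # --- simulate ------------------------------------------------------
        t0 = time.time()
        prov.note("stage simulate: start")
        sim_dir = out / "sim"
        study = StudyConfig(
            n_per_group=config.n_per_group, groups=tuple(config.groups),
            effect=config.effect, noise_sd=config.noise_sd,
            block_r=config.block_r, ppm_step=config.ppm_step,
            spectral_noise_sd=config.spectral_noise_sd,
            global_shift_sd=config.global_shift_sd,
            seed=config.stage_seed("simulate"),
        )
        truth = simulate_study(study, sim_dir)
        outputs = sorted(sim_dir.rglob("*.txt")) + [
            sim_dir / "manifest.csv", sim_dir / "aa_table.csv", sim_dir / "truth.json",
        ]
        prov.record("simulate", {"n_per_group": config.n_per_group,
                                 "groups": list(config.groups)},
                    study.seed, outputs, t0)

        # --- preprocess ----------------------------------------------------
        t0 = time.time()
        prov.note("stage preprocess: start")
        manifest = pd.read_csv(sim_dir / "manifest.csv")
        spectra = [
            preprocess.read_spectrum(sim_dir / "spectra" / f"{sid}.txt", sample_id=sid)
            for sid in manifest["sample_id"]
        ]
        if config.align:
            spectra, _ = preprocess.align_spectra(
                spectra, max_shift=config.max_shift, segment=config.segment
            )
        groups = pd.Series(manifest["group"].to_numpy(), index=manifest["sample_id"])
        bm = preprocess.bucket(
            spectra, width=config.bucket_width, ppm_min=config.ppm_min,
            ppm_max=config.ppm_max, exclusions=config.exclusions, groups=groups,
        )
        bm = preprocess.pqn_normalize(bm)
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        bm.to_csv(pre_dir / "buckets_pqn.csv")
        scaled = preprocess.scale(bm, method="pareto")
        scaled.to_csv(pre_dir / "buckets_pareto.csv")
        prov.record(
            "preprocess",
            {"bucket_width": config.bucket_width, "align": config.align,
             "range": [config.ppm_min, config.ppm_max],
             "exclusions": [list(e) for e in config.exclusions]},
            None,
            [pre_dir / "buckets_pqn.csv", pre_dir / "buckets_pqn.csv.json",
             pre_dir / "buckets_pareto.csv", pre_dir / "buckets_pareto.csv.json"],
            t0,
        )

        # --- model (OPLS-DA per contrast on buckets) -----------------------
        t0 = time.time()
        prov.note("stage model: start")
        model_dir = out / "models"
        model_dir.mkdir(exist_ok=True)
        contrast_groups = [g for g in config.groups if g != "M"]
        model_seed = config.stage_seed("model")
        model_outputs = []
        for g in contrast_groups:
            sel = groups.isin([g, "M"])
            X = scaled.data.loc[sel.to_numpy()].to_numpy()
            y = groups[sel].to_numpy()
            rep = chemometrics.permutation_test(
                X, y, n_orth=config.n_orth, B=config.n_permutations,
                folds=config.folds, cv_repeats=config.permutation_cv_repeats,
                observed_cv_repeats=config.cv_repeats,
                seed=_stage_seed(model_seed, g),
            )
            payload = rep.to_dict()
            payload["contrast"] = f"{g}_vs_M"
            path = model_dir / f"oplsda_{g}_vs_M.json"
            path.write_text(json.dumps(payload, indent=1))
            model_outputs.append(path)
            summary["contrasts"][g] = {
                "r2y": payload["observed"]["r2y"],
                "q2": payload["observed"]["q2"],
                "auroc": payload["observed"]["auroc"],
                "misclassification": payload["observed"]["misclassification"],
                "p_q2": payload["p_values"]["q2"],
            }
        prov.record("model", {"n_orth": config.n_orth, "B": config.n_permutations},
                    model_seed, model_outputs, t0)

        # --- screen (univariate on the AA table) ---------------------------
        t0 = time.time()
        prov.note("stage screen: start")
        screen_dir = out / "screen"
        screen_dir.mkdir(exist_ok=True)
        aa = pd.read_csv(sim_dir / "aa_table.csv", index_col="sample_id")
        screen_outputs = []
        diffs = {}
        for g in contrast_groups:
            res = univariate.differential_analysis(
                aa, groups, numerator=g, denominator="M", alpha=config.alpha
            )
            diffs[g] = res
            path = screen_dir / f"differential_{g}_vs_M.csv"
            res.to_csv(path)
            screen_outputs.append(path)
            summary["contrasts"][g]["n_differential"] = int(
                (res["direction"] != "unchanged").sum()
            )
        z, stars = univariate.heatmap_table(aa, groups, reference="NC",
                                            alpha=config.alpha)
        z.to_csv(screen_dir / "heatmap_z.csv")
        stars.to_csv(screen_dir / "heatmap_stars.csv")
        screen_outputs += [screen_dir / "heatmap_z.csv", screen_dir / "heatmap_stars.csv"]
        prov.record("screen", {"alpha": config.alpha}, None, screen_outputs, t0)

        # --- network -------------------------------------------------------
        t0 = time.time()
        prov.note("stage network: start")
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        similarity = network.load_similarity_pairs()
        net_outputs = []
        for g in contrast_groups:
            res = diffs[g]
            sel = groups.isin([g, "M"])
            n_diff = int((res["direction"] != "unchanged").sum())
            if n_diff >= 2:
                graph = network.build_differential_network(
                    res, aa.loc[sel.to_numpy()],
                    r_threshold=config.r_threshold, p_threshold=config.p_threshold,
                    similarity=similarity,
                    similarity_threshold=config.similarity_threshold,
                    contrast=f"{g}_vs_M",
                )
            else:  # too few differential metabolites: record an empty network
                import networkx as nx

                graph = nx.MultiGraph(contrast=f"{g}_vs_M",
                                      r_threshold=config.r_threshold,
                                      p_threshold=config.p_threshold)
            path = net_dir / f"network_{g}_vs_M.graphml"
            network.export_graph(graph, path, format="graphml")
            network.export_graph(graph, net_dir / f"network_{g}_vs_M.tsv", format="tsv")
            net_outputs += [path, net_dir / f"network_{g}_vs_M.tsv",
                            net_dir / f"network_{g}_vs_M.tsv.nodes"]
            hubs = network.hub_ranking(graph)
            summary["contrasts"][g]["n_edges"] = graph.number_of_edges()
            summary["contrasts"][g]["top_hub"] = (
                hubs["metabolite"].iloc[0] if len(hubs) else None
            )
        prov.record(
            "network",
            {"r_threshold": config.r_threshold, "p_threshold": config.p_threshold},
            None, net_outputs, t0,
        )

        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        prov.note("run complete")
        return summary
    except Exception as exc:
        prov.note(f"FAILED: {exc}")
        raise
    finally:
        prov.close()


def run_hashes(out_dir) -> dict:
    """SHA-256 of every result file of a run (for determinism checks)."""
    out = Path(out_dir)
    hashes = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("run.log", "provenance.json"):
            hashes[str(p.relative_to(out))] = _sha256(p)
    return hashes
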