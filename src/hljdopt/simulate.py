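"""Synthetic cohort generator for the eleven-group MCAO metabolomics study.

Generates, with recorded ground truth, the two data modalities the analysis
consumes:

* 1H-NMR-like spectra (Lorentzian peaks on a 0.2-10 ppm axis, optional broad
  residual-water band, linear baseline, additive Gaussian noise), one
  two-column text file per sample;
* a 23-amino-acid concentration table on the printed targeted panel.

Concentrations follow a log-normal model: for sample *j* of group *g* and
metabolite *m*,

    c_jm = baseline_m * 2**fc(g, m) * exp(eps_jm),

with ``eps`` multivariate normal on the log scale (SD ``noise_sd``,
block-structured correlation).  Group mean *ratios* therefore equal
``2**fc`` exactly, matching the pipeline's fold-change statistics.

The default MCAO-vs-sham preset plants the published direction list: 14
amino acids up (Glu, Asp, Ile, Leu, GABA, Gly, Thr, Ala, Lys, Phe, Met,
Trp, Ser, Orn) and 4 down (2-ABA, Arg, Tau, Pro) in the model group, with
each treatment group recovering a configurable fraction of the insult.
Correlation blocks are seeded around Thr, Ala and Val, echoing the three
amino-acid clusters the study observes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

WATER_BAND = (4.65, 5.25)
PPM_RANGE = (0.2, 10.0)

#: The 23-amino-acid targeted panel, in printed order.
AA_PANEL = (
    "Asp", "Glu", "Cys", "Ser", "Gln", "Gly", "His", "Tau", "GABA", "Thr",
    "Arg", "Ala", "Pro", "2-ABA", "Tyr", "Val", "Met", "Ile", "Leu", "Phe",
    "Trp", "Orn", "Lys",
)

#: Published MCAO-vs-sham directions: +1 increased, -1 decreased, 0 unchanged.
AA_DIRECTIONS = {
    "Glu": 1, "Asp": 1, "Ile": 1, "Leu": 1, "GABA": 1, "Gly": 1, "Thr": 1,
    "Ala": 1, "Lys": 1, "Phe": 1, "Met": 1, "Trp": 1, "Ser": 1, "Orn": 1,
    "2-ABA": -1, "Arg": -1, "Tau": -1, "Pro": -1,
    "Cys": 0, "Gln": 0, "His": 0, "Tyr": 0, "Val": 0,
}

#: Default correlation blocks, seeded around Thr, Ala and Val.
DEFAULT_BLOCKS = {
    "threonine": ("Thr", "Gln", "Gly", "Ile", "Leu"),
    "alanine": ("Ala", "Ser", "2-ABA", "Asp", "Lys"),
    "valine": ("Val", "His", "Cys", "Glu", "Met"),
}

STUDY_GROUPS = ("NC", "M") + tuple(f"F{i}" for i in range(1, 10))

#: Fraction of the MCAO insult each group recovers (1 = back to sham).
#: NC carries no insult; M none of the recovery.  F9 is the near-complete
#: responder, F1 and F5 partial, the remainder weak, mirroring the ranking
#: the study reports.
DEFAULT_RECOVERY = {
    "NC": None, "M": 0.0,
    "F1": 0.7, "F2": 0.3, "F3": 0.25, "F4": 0.2, "F5": 0.7,
    "F6": 0.3, "F7": 0.25, "F8": 0.2, "F9": 0.9,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration (e.g. non-PSD covariance)."""


def default_aa_panel() -> list[str]:
    """The 23-amino-acid targeted panel, in printed order."""
    return list(AA_PANEL)


@dataclass(frozen=True)
class MetaboliteDef:
    """One metabolite's NMR signature: weighted Lorentzian peaks.

    peaks: list of (center_ppm, half_width_at_half_max_ppm, area_weight);
    weights are positive and sum to one, so a metabolite at unit
    concentration contributes unit integrated area.
    """

    name: str
    peaks: tuple  # ((center, hwhm, weight), ...)
    baseline_conc: float = 1.0

    def __post_init__(self):
        w = np.array([p[2] for p in self.peaks], dtype=float)
        if len(w) == 0 or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ConfigurationError(
                f"{self.name}: peak area weights must be positive and sum to 1"
            )
        for c, hw, _ in self.peaks:
            if not (PPM_RANGE[0] <= c <= PPM_RANGE[1]):
                raise ConfigurationError(f"{self.name}: peak at {c} ppm out of range")
            if WATER_BAND[0] <= c <= WATER_BAND[1]:
                raise ConfigurationError(
                    f"{self.name}: peak at {c} ppm inside the water band"
                )
            if hw <= 0:
                raise ConfigurationError(f"{self.name}: non-positive half-width")
        if self.baseline_conc <= 0:
            raise ConfigurationError(f"{self.name}: baseline concentration must be > 0")


def default_metabolite_library() -> list[MetaboliteDef]:
    """A small brain-extract-like library of assigned metabolites.

    Chemical shifts are literature-typical for aqueous brain extracts;
    multiplets are encoded as a few weighted Lorentzians.  All centers lie
    inside 0.2-10 ppm and outside the 4.65-5.25 ppm water band.
    """
    specs = [
        ("Lactate", ((1.33, 0.004, 0.75), (4.11, 0.004, 0.25)), 6.0),
        ("NAA", ((2.02, 0.004, 0.6), (2.49, 0.005, 0.2), (2.67, 0.005, 0.2)), 5.0),
        ("Creatine", ((3.03, 0.004, 0.6), (3.93, 0.004, 0.4)), 4.0),
        ("Glycerol", ((3.56, 0.005, 0.5), (3.65, 0.005, 0.5)), 2.0),
        ("Ala", ((1.48, 0.004, 0.75), (3.78, 0.004, 0.25)), 2.0),
        ("Leu", ((0.96, 0.005, 0.7), (1.71, 0.005, 0.3)), 1.5),
        ("Ile", ((1.01, 0.005, 0.6), (1.26, 0.005, 0.4)), 1.0),
        ("Val", ((0.99, 0.004, 0.5), (1.04, 0.004, 0.5)), 1.0),
        ("Glu", ((2.08, 0.005, 0.4), (2.35, 0.005, 0.4), (3.75, 0.004, 0.2)), 8.0),
        ("GABA", ((1.90, 0.005, 0.4), (2.29, 0.005, 0.3), (3.01, 0.004, 0.3)), 2.5),
        ("Gly", ((3.55, 0.003, 1.0), ), 3.0),
        ("Thr", ((1.32, 0.004, 0.5), (4.25, 0.004, 0.5)), 2.0),
        ("Tau", ((3.25, 0.004, 0.5), (3.42, 0.004, 0.5)), 5.0),
        ("Asp", ((2.68, 0.005, 0.5), (2.80, 0.005, 0.5)), 3.0),
    ]
    return [MetaboliteDef(n, p, b) for n, p, b in specs]

#: MCAO direction for the non-amino-acid library members.
EXTRA_DIRECTIONS = {"Lactate": 1, "NAA": -1, "Creatine": 0, "Glycerol": 1}


@dataclass
class CohortTruth:
    """Ground truth of one simulated cohort."""

    sample_ids: list
    groups: list  # group label per sample
    concentrations: pd.DataFrame  # samples x metabolites
    log2_fc: pd.DataFrame  # groups x metabolites, vs the reference group
    blocks: dict  # metabolite -> block name (absent = independent)
    seed: int

    def differential_set(self, group: str) -> set:
        """Metabolites with nonzero planted log2 FC in *group*."""
        fc = self.log2_fc.loc[group]
        return set(fc.index[fc != 0])

    def to_json(self, path) -> None:
        payload = {
            "sample_ids": list(self.sample_ids),
            "groups": list(self.groups),
            "metabolites": list(self.concentrations.columns),
            "concentrations": self.concentrations.to_numpy().tolist(),
            "log2_fc": {g: self.log2_fc.loc[g].to_dict() for g in self.log2_fc.index},
            "blocks": dict(self.blocks),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        conc = pd.DataFrame(
            d["concentrations"], index=d["sample_ids"], columns=d["metabolites"]
        )
        fc = pd.DataFrame(d["log2_fc"]).T.reindex(columns=d["metabolites"])
        return cls(
            sample_ids=d["sample_ids"], groups=d["groups"], concentrations=conc,
            log2_fc=fc, blocks=d["blocks"], seed=d["seed"],
        )


def _block_correlation(names, blocks, block_r):
    """Block-structured correlation matrix over *names*."""
    p = len(names)
    r = np.eye(p)
    label = {m: b for b, members in _as_block_map(blocks).items() for m in members}
    for i, a in enumerate(names):
        for j in range(i + 1, p):
            b = names[j]
            if a in label and label.get(b) == label[a]:
                r[i, j] = r[j, i] = block_r
    return r


def _as_block_map(blocks):
    if blocks is None:
        return {}
    if all(isinstance(v, (list, tuple, set)) for v in blocks.values()):
        return {k: tuple(v) for k, v in blocks.items()}
    # metabolite -> block form
    out = {}
    for m, b in blocks.items():
        out.setdefault(b, []).append(m)
    return {k: tuple(v) for k, v in out.items()}


def simulate_concentrations(
    groups: dict,
    baselines: pd.Series,
    log2_fc: pd.DataFrame,
    blocks=None,
    block_r: float = 0.7,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> CohortTruth:
    """Draw a log-normal concentration cohort with planted effects.

    Parameters
    ----------
    groups : {group label: n samples} (insertion order preserved)
    baselines : positive baseline concentration per metabolite
    log2_fc : groups x metabolites planted log2 fold changes vs baseline
    blocks : block name -> members (or metabolite -> block); within-block
        log-scale correlation is ``block_r``, between-block 0
    noise_sd : log-scale (natural log) noise SD, >= 0
    """
    names = list(baselines.index)
    if (baselines <= 0).any():
        raise ConfigurationError("all baseline concentrations must be > 0")
    if noise_sd < 0:
        raise ConfigurationError("noise SD must be >= 0")
    log2_fc = log2_fc.reindex(index=list(groups), columns=names).fillna(0.0)

    corr = _block_correlation(names, blocks, block_r)
    cov = (noise_sd ** 2) * corr
    if noise_sd > 0:
        try:
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(names)))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("block covariance is not positive semidefinite") from exc

    rng = np.random.default_rng(seed)
    rows, sample_ids, labels = [], [], []
    base = baselines.to_numpy(dtype=float)
    for g, n in groups.items():
        if n < 1:
            raise ConfigurationError(f"group {g!r} needs at least 1 sample")
        mult = np.power(2.0, log2_fc.loc[g].to_numpy(dtype=float))
        for k in range(n):
            eps = chol @ rng.standard_normal(len(names)) if noise_sd > 0 else 0.0
            rows.append(base * mult * np.exp(eps))
            sample_ids.append(f"{g}_{k + 1:02d}")
            labels.append(g)
    conc = pd.DataFrame(rows, index=sample_ids, columns=names)

    block_map = {m: b for b, mem in _as_block_map(blocks).items() for m in mem}
    return CohortTruth(
        sample_ids=sample_ids, groups=labels, concentrations=conc,
        log2_fc=log2_fc, blocks=block_map, seed=int(seed),
    )


def mcao_log2_fc(
    metabolites,
    effect: float = 1.0,
    recovery: dict | None = None,
    reference: str = "NC",
) -> pd.DataFrame:
    """Planted log2-FC matrix for the eleven-group study, vs the sham group.

    The model group gets ``direction * effect``; each treatment group g gets
    ``(1 - recovery[g]) * direction * effect``.
    """
    recovery = dict(DEFAULT_RECOVERY if recovery is None else recovery)
    directions = {**AA_DIRECTIONS, **EXTRA_DIRECTIONS}
    rows = {}
    for g, rho in recovery.items():
        if g == reference or rho is None:
            rows[g] = {m: 0.0 for m in metabolites}
        else:
            rows[g] = {
                m: (1.0 - rho) * directions.get(m, 0) * effect for m in metabolites
            }
    return pd.DataFrame(rows).T.reindex(columns=list(metabolites)).fillna(0.0)


def lorentzian(ppm: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian line shape."""
    return (hwhm / np.pi) / ((ppm - center) ** 2 + hwhm ** 2)


def simulate_spectrum(
    concentrations: pd.Series,
    library,
    ppm: np.ndarray,
    baseline=(0.0, 0.0),
    noise_sd: float = 0.0,
    water_artifact: float = 0.0,
    rng=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one sample's spectrum from its true concentrations.

    intensity = sum_m c_m * sum_k w_mk * Lorentzian(ppm; c_mk, g_mk)
                + b0 + b1*ppm + optional broad water band + Gaussian noise.

    Returns (ppm, intensity) with ppm exactly as supplied.
    """
    ppm = np.asarray(ppm, dtype=float)
    d = np.diff(ppm)
    if len(ppm) < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm axis must be strictly monotone")
    intensity = np.zeros_like(ppm)
    for met in library:
        c = float(concentrations.get(met.name, 0.0))
        if c == 0.0:
            continue
        for center, hwhm, weight in met.peaks:
            intensity += c * weight * lorentzian(ppm, center, hwhm)
    b0, b1 = baseline
    intensity = intensity + b0 + b1 * ppm
    if water_artifact:
        intensity += water_artifact * lorentzian(ppm, 4.9, 0.15)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        intensity = intensity + rng.normal(0.0, noise_sd, size=ppm.shape)
    return ppm, intensity


@dataclass
class StudyConfig:
    """Configuration of one simulated eleven-group study."""

    n_per_group: int = 10
    groups: tuple = STUDY_GROUPS
    effect: float = 1.0  # |log2 FC| planted in the model group
    recovery: dict | None = None
    noise_sd: float = 0.3  # log-scale concentration noise
    block_r: float = 0.7
    ppm_step: float = 0.001
    spectral_noise_sd: float = 0.002
    baseline: tuple = (0.0, 0.0)
    water_artifact: float = 0.0
    global_shift_sd: float = 0.0  # optional per-sample ppm shift (exercises alignment)
    seed: int = 0


def simulate_study(config: StudyConfig, out_dir) -> CohortTruth:
    """Simulate a full study and write its files under *out_dir*.

    Writes one ``<sample>.txt`` two-column spectrum per sample (descending
    ppm), ``manifest.csv`` (sample_id, group), ``aa_table.csv`` (samples x
    23-AA panel) and ``truth.json``.  All randomness derives from
    ``config.seed``; identical config + seed gives byte-identical files.
    """
    out = Path(out_dir)
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    if "NC" not in config.groups or "M" not in config.groups:
        raise ConfigurationError("groups must include at least NC and M")

    library = default_metabolite_library()
    lib_names = [m.name for m in library]
    all_names = list(dict.fromkeys(list(AA_PANEL) + lib_names))
    baselines = pd.Series(1.0, index=all_names)
    for m in library:
        baselines[m.name] = m.baseline_conc
    # amino acids not in the spectral library get modest brain-like levels
    for aa in AA_PANEL:
        if aa not in lib_names:
            baselines[aa] = 2.0

    fc = mcao_log2_fc(all_names, effect=config.effect, recovery=config.recovery)
    fc = fc.reindex(index=list(config.groups)).fillna(0.0)
    truth = simulate_concentrations(
        {g: config.n_per_group for g in config.groups},
        baselines, fc, blocks=DEFAULT_BLOCKS, block_r=config.block_r,
        noise_sd=config.noise_sd, seed=config.seed,
    )

    ppm = np.arange(PPM_RANGE[0], PPM_RANGE[1] + config.ppm_step / 2, config.ppm_step)
    ppm_desc = ppm[::-1]
    rng = np.random.default_rng(_stage_seed(config.seed, "spectra"))
    manifest = []
    for sid, grp in zip(truth.sample_ids, truth.groups):
        axis = ppm_desc
        if config.global_shift_sd > 0:
            axis = ppm_desc + rng.normal(0.0, config.global_shift_sd)
        _, intensity = simulate_spectrum(
            truth.concentrations.loc[sid], library, axis,
            baseline=config.baseline, noise_sd=config.spectral_noise_sd,
            water_artifact=config.water_artifact, rng=rng,
        )
        path = spectra_dir / f"{sid}.txt"
        with open(path, "w") as fh:
            fh.write("# ppm\tintensity\n")
            for x, y in zip(ppm_desc, intensity):
                fh.write(f"{x:.6f}\t{y:.8e}\n")
        manifest.append({"sample_id": sid, "group": grp})

    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    aa = truth.concentrations[list(AA_PANEL)]
    aa.to_csv(out / "aa_table.csv", index_label="sample_id", float_format="%.8g")
    truth.to_json(out / "truth.json")
    return truth


def _stage_seed(master_seed: int, stage: str) -> int:
    """Stable sub-seed derived from the master seed and a stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2 ** 31)
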