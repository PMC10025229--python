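"""Synthetic cohort generator with known ground truth.

Emulates the study design the analysis targets: three groups (normal
controls NC, obstructive sleep apnea before CPAP treatment OSA_pre, and
after treatment OSA_post), each subject carrying

* a set of perivascular-space concentration-time curves drawn from two
  latent flow-pattern populations — type I (periarterial: high peak, steep
  wash-in) and type II (perivenous: low, shallow) — simulated through the
  extended Tofts model plus additive Gaussian concentration noise;
* axial slice phantoms with PVS / ventricle / reference-region masks whose
  areas scale with disease severity;
* clinical covariates (AHI, ODI, LSaO2, BMI, MMSE, MoCA, PSQI, ESS) linked
  monotonically to a per-subject latent severity.

Group effects are multiplicative and centred within group, so that setting
all multipliers to one and equalising the latent-severity distributions
makes the group label exchangeable (the null configuration used for
calibration).  Defaults encode the study conditions: group sizes (25, 11,
13), a 0.1 mmol/kg dose, a 9 min 59 s acquisition sampled at 5 s, type-I
curve fractions 35.66 % (NC) / 43.84 % (OSA_pre) / 46.08 % (OSA_post), and
effect directions: OSA_pre type-I curves have a higher peak and lower
wash-out than NC; OSA_post type-II curves have a higher peak.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dce import AIF, CTC, ToftsParams, generate_aif, tofts_forward_batch
from .morphometry import RoiMask, SliceImage
from .stats import Subject

__all__ = [
    "SimulationConfig",
    "SliceSet",
    "SyntheticCohort",
    "generate_cohort",
    "generate_slice_masks",
    "null_config",
    "simulate_ctc",
    "write_cohort",
]

GROUPS = ("NC", "OSA_pre", "OSA_post")

#: Default AIF shape for the simulated acquisition: a bolus-dominant
#: bi-exponential (fast first-pass component plus a modest slow tail).  With
#: this input the perivascular curves peak within the first minutes and then
#: decay at a rate governed by kep, so the simulated wash-out rate genuinely
#: reflects efflux - the regime the flow-pattern typing relies on.
DEFAULT_AIF_SHAPE: dict[str, float] = {
    "a1_kg_per_l": 8.0,
    "m1_per_min": 2.0,
    "a2_kg_per_l": 0.4,
    "m2_per_min": 0.30,
    "onset_s": 30.0,
    "rise_s": 10.0,
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ParamDist:
    """Independent truncated-normal distributions for Tofts parameters."""

    ktrans_mean: float
    ktrans_sd: float
    kep_mean: float
    kep_sd: float
    vp_mean: float
    vp_sd: float


@dataclass
class GroupEffects:
    """Multiplicative group effects and within-group severity couplings.

    ``typeI_peak_mult`` / ``typeI_washout_mult`` act on OSA_pre type-I curves
    (Ktrans & vp, respectively kep); ``typeII_peak_mult`` acts on OSA_post
    type-II curves.  The couplings modulate every subject's curves by
    ``exp(+-c * (s - E[s | group]))`` so group means are untouched while
    within-group features track severity.
    """

    typeI_peak_mult: float = 1.1
    typeI_washout_mult: float = 0.5
    typeII_peak_mult: float = 1.3
    peak_severity_coupling: float = 0.05
    washout_severity_coupling: float = 0.30


@dataclass
class SimulationConfig:
    seed: int = 0
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {"NC": 25, "OSA_pre": 11, "OSA_post": 13}
    )
    # legend-derived per-group mean CTC counts; truncated-Poisson (>= 1)
    curves_per_subject_mean: dict[str, float] = field(
        default_factory=lambda: {"NC": 9.44, "OSA_pre": 23.0, "OSA_post": 14.0}
    )
    # acquisition: 9 min 59 s total, 5 s frame spacing
    frame_interval_s: float = 5.0
    duration_s: float = 599.0
    dose_mmol_per_kg: float = 0.1
    aif_shape: dict[str, float] | None = field(
        default_factory=lambda: dict(DEFAULT_AIF_SHAPE)
    )
    type1_fraction: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.3566, "OSA_pre": 0.4384, "OSA_post": 0.4608}
    )
    typeI_params: ParamDist = field(
        default_factory=lambda: ParamDist(0.13, 0.022, 0.35, 0.042, 0.015, 0.004)
    )
    typeII_params: ParamDist = field(
        default_factory=lambda: ParamDist(0.03, 0.006, 0.30, 0.045, 0.006, 0.002)
    )
    group_effects: GroupEffects = field(default_factory=GroupEffects)
    # additive concentration noise; default gives SNR ~ 20 at the mean
    # type-I peak under the default acquisition and dose
    noise_sd: float = 0.0018
    # latent severity ~ N(mean, sd) per group
    severity_mean: dict[str, float] = field(
        default_factory=lambda: {"NC": -2.0, "OSA_pre": 0.0, "OSA_post": 0.0}
    )
    severity_sd: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.35, "OSA_pre": 1.0, "OSA_post": 1.0}
    )
    # covariate = intercept + slope * severity + N(0, noise), clipped
    covariate_model: dict[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: {
            "AHI": (28.9, 15.0, 3.0, 0.0, 120.0),
            "ODI": (30.7, 17.0, 4.0, 0.0, 120.0),
            "LSaO2": (79.7, -7.0, 2.0, 40.0, 100.0),
            "BMI": (28.4, 1.5, 1.2, 15.0, 45.0),
            "MMSE": (27.7, -1.8, 0.8, 0.0, 30.0),
            "MoCA": (27.0, -1.9, 0.8, 0.0, 30.0),
            "PSQI": (8.1, 3.0, 1.2, 0.0, 21.0),
            "ESS": (6.3, 2.5, 1.0, 0.0, 24.0),
        }
    )
    # slice phantom geometry
    include_slices: bool = True
    image_size: int = 192
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    # base relative area (fraction of reference region) per structure and the
    # severity -> area coupling exp(beta * (severity - NC mean severity))
    base_area_fraction: dict[str, float] = field(
        default_factory=lambda: {
            "frontal_PVS": 0.012,
            "basal_ganglia_PVS": 0.015,
            "lateral_ventricles": 0.078,
            "fourth_ventricle": 0.016,
        }
    )
    morphometry_severity_beta: dict[str, float] = field(
        default_factory=lambda: {
            "frontal_PVS": 0.40,
            "basal_ganglia_PVS": 0.35,
            "lateral_ventricles": 0.25,
            "fourth_ventricle": 0.20,
        }
    )
    morphometry_noise_cv: float = 0.08  # lognormal area jitter per subject
    image_noise_sd: float = 3.0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_subjects.values()):
            raise ValueError("subject counts must be >= 1")
        if any(m < 1 for m in self.curves_per_subject_mean.values()):
            raise ValueError("mean curves per subject must be >= 1")
        if self.frame_interval_s <= 0 or self.duration_s <= self.frame_interval_s:
            raise ValueError("invalid time grid")
        if self.dose_mmol_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for d in (self.typeI_params, self.typeII_params):
            if min(d.ktrans_sd, d.kep_sd, d.vp_sd) < 0:
                raise ValueError("parameter SDs must be non-negative")
        ge = self.group_effects
        if min(ge.typeI_peak_mult, ge.typeI_washout_mult, ge.typeII_peak_mult) <= 0:
            raise ValueError("effect multipliers must be positive")
        if not all(0 <= f <= 1 for f in self.type1_fraction.values()):
            raise ValueError("type-I fractions must lie in [0, 1]")
        if self.image_size < 16 or min(self.pixel_spacing) <= 0:
            raise ValueError("invalid phantom geometry")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 1e-9, self.frame_interval_s)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pixel_spacing"] = list(self.pixel_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "typeI_params" in d and isinstance(d["typeI_params"], dict):
            d["typeI_params"] = ParamDist(**d["typeI_params"])
        if "typeII_params" in d and isinstance(d["typeII_params"], dict):
            d["typeII_params"] = ParamDist(**d["typeII_params"])
        if "group_effects" in d and isinstance(d["group_effects"], dict):
            d["group_effects"] = GroupEffects(**d["group_effects"])
        if "pixel_spacing" in d:
            d["pixel_spacing"] = tuple(d["pixel_spacing"])
        if "covariate_model" in d:
            d["covariate_model"] = {
                k: tuple(v) for k, v in d["covariate_model"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def null_config(base: SimulationConfig | None = None) -> SimulationConfig:
    """A configuration with every group effect switched off.

    All multiplicative effects are 1, the latent-severity distribution, the
    type-I fraction and the curve-count distribution are identical across
    groups, so the group label is exchangeable for every downstream feature.
    """
    cfg = base or SimulationConfig()
    cfg = dataclasses.replace(
        cfg,
        group_effects=GroupEffects(1.0, 1.0, 1.0,
                                   cfg.group_effects.peak_severity_coupling,
                                   cfg.group_effects.washout_severity_coupling),
        type1_fraction={g: 0.40 for g in GROUPS},
        curves_per_subject_mean={g: cfg.curves_per_subject_mean["NC"] for g in GROUPS},
        severity_mean={g: 0.0 for g in GROUPS},
        severity_sd={g: 1.0 for g in GROUPS},
    )
    return cfg


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass
class SliceSet:
    """One axial phantom level: image, masks and ground-truth areas."""

    level: str
    image: SliceImage
    masks: dict[str, RoiMask]
    true_areas_mm2: dict[str, float]


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    seed: int
    subjects: list[Subject]
    severity: dict[str, float]
    aif: AIF
    ctcs: list[CTC]
    truth: dict[str, dict]  # roi_id -> {"type", "params", "subject_id"}
    slices: dict[str, dict[str, SliceSet]]  # subject_id -> level -> SliceSet

    def subjects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.subjects])

    def ctc_frame(self) -> pd.DataFrame:
        """Long-format curve table: subject_id, roi_id, t_seconds, concentration."""
        frames = [
            pd.DataFrame({
                "subject_id": c.subject_id,
                "roi_id": c.roi_id,
                "t_seconds": c.t,
                "concentration": c.C,
            })
            for c in self.ctcs
        ]
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Curve simulation
# ---------------------------------------------------------------------------

def simulate_ctc(
    params: ToftsParams,
    aif: AIF,
    noise_sd: float,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    roi_id: str = "",
) -> CTC:
    """Forward-simulate one noisy CTC from Tofts parameters and an AIF."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clean = tofts_forward_batch(
        np.array([params.Ktrans]), np.array([params.kep]), np.array([params.vp]), aif
    )[0]
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return CTC(subject_id=subject_id, roi_id=roi_id, t=aif.t, C=noisy)


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    for _ in range(1000):
        n = int(rng.poisson(mean))
        if n >= 1:
            return n
    return 1


def _draw_params(
    rng: np.random.Generator, dist: ParamDist, peak_factor: float, washout_factor: float
) -> tuple[float, float, float]:
    ktrans = max(rng.normal(dist.ktrans_mean, dist.ktrans_sd), 1e-3) * peak_factor
    kep = max(rng.normal(dist.kep_mean, dist.kep_sd), 0.05) * washout_factor
    vp = float(np.clip(rng.normal(dist.vp_mean, dist.vp_sd), 0.0, 0.2)) * peak_factor
    # keep ve + vp physically plausible
    ktrans = min(ktrans, 0.9 * kep)
    return ktrans, kep, vp


# ---------------------------------------------------------------------------
# Slice phantoms
# ---------------------------------------------------------------------------

def _disc(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(n: int, center: tuple[float, float], a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    return ((xx - center[1]) / a) ** 2 + ((yy - center[0]) / b) ** 2 <= 1.0


def _area_multiplier(cfg: SimulationConfig, structure: str, severity: float) -> float:
    beta = cfg.morphometry_severity_beta[structure]
    return float(np.exp(beta * (severity - cfg.severity_mean["NC"])))


def generate_slice_masks(
    config: SimulationConfig,
    subject: Subject,
    seed: int | np.random.Generator = 0,
    severity: float | None = None,
) -> dict[str, SliceSet]:
    """Axial slice phantoms for one subject, one per anatomical level.

    Each level holds a reference region (brain / basal ganglia / cerebellum
    disc or ellipse) and the structure of interest (PVS pixels scattered
    inside the region; ventricle ellipses), with the structure area scaled by
    ``exp(beta * (severity - NC mean severity))`` so enlargement tracks
    disease severity.  True areas are the painted pixel counts times the
    pixel area.  A structure area request exceeding its reference region
    raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if severity is None:
        # monotone in AHI: invert the default covariate link
        icpt, slope, _, _, _ = config.covariate_model["AHI"]
        severity = ((subject.AHI if subject.AHI is not None else icpt) - icpt) / slope
    n = config.image_size
    spacing = config.pixel_spacing
    pixel_area = spacing[0] * spacing[1]
    scale = n / 192.0  # geometry defined at the 192-pixel reference size
    c = (n / 2.0, n / 2.0)
    jitter = float(np.exp(rng.normal(0.0, config.morphometry_noise_cv)))

    levels: dict[str, SliceSet] = {}

    def build_level(level: str, region_label: str, region: np.ndarray,
                    structure_label: str, structure: np.ndarray) -> None:
        img = np.zeros((n, n), dtype=float)
        img[region] = 100.0
        img[structure] = 200.0
        if config.image_noise_sd > 0:
            img = np.clip(img + rng.normal(0.0, config.image_noise_sd, img.shape), 0, None)
        image = SliceImage(pixels=img, pixel_spacing=spacing)
        masks = {
            region_label: RoiMask(region, region_label, spacing),
            structure_label: RoiMask(structure, structure_label, spacing),
        }
        areas = {
            region_label: float(region.sum()) * pixel_area,
            structure_label: float(structure.sum()) * pixel_area,
        }
        levels[level] = SliceSet(level=level, image=image, masks=masks,
                                 true_areas_mm2=areas)

    def scatter_pvs(region: np.ndarray, structure: str) -> np.ndarray:
        mult = _area_multiplier(config, structure, severity) * jitter
        target_px = int(round(
            config.base_area_fraction[structure] * region.sum() * mult
        ))
        if target_px > region.sum():
            raise ValueError(
                f"requested {structure} area exceeds its reference region"
            )
        mask = np.zeros_like(region)
        if target_px > 0:
            flat = np.flatnonzero(region)
            chosen = rng.choice(flat, size=target_px, replace=False)
            mask.flat[chosen] = True
        return mask

    # frontal level
    brain_f = _disc(n, c, 80 * scale)
    build_level("frontal", "brain_at_frontal_level", brain_f,
                "frontal_PVS", scatter_pvs(brain_f, "frontal_PVS"))

    # basal ganglia level
    bg = _ellipse(n, c, 60 * scale, 40 * scale)
    build_level("basal_ganglia", "basal_ganglia_total", bg,
                "basal_ganglia_PVS", scatter_pvs(bg, "basal_ganglia_PVS"))

    # lateral ventricle level: two mirrored ellipses, axes scale with area
    brain_v = _disc(n, c, 80 * scale)
    mult = _area_multiplier(config, "lateral_ventricles", severity) * jitter
    base_frac = config.base_area_fraction["lateral_ventricles"]
    ax_scale = float(np.sqrt(mult * base_frac / 0.078))
    # long axis anterior-posterior (rows), mirrored pair about the midline
    a0, b0 = 10 * scale, 25 * scale
    lv = (
        _ellipse(n, (c[0], c[1] - 22 * scale), a0 * ax_scale, b0 * ax_scale)
        | _ellipse(n, (c[0], c[1] + 22 * scale), a0 * ax_scale, b0 * ax_scale)
    ) & brain_v
    if lv.sum() > brain_v.sum():  # pragma: no cover - geometry guard
        raise ValueError("requested ventricle area exceeds the brain region")
    build_level("ventricle", "brain_at_ventricle_level", brain_v,
                "lateral_ventricles", lv)

    # fourth ventricle level
    cereb = _disc(n, c, 50 * scale)
    mult4 = _area_multiplier(config, "fourth_ventricle", severity) * jitter
    s4 = float(np.sqrt(mult4))
    v4 = _ellipse(n, c, 8 * scale * s4, 5 * scale * s4) & cereb
    build_level("fourth", "cerebellum_at_fourth_level", cereb,
                "fourth_ventricle", v4)

    return levels


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_covariates(
    rng: np.random.Generator, cfg: SimulationConfig, severity: float
) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, (icpt, slope, noise, lo, hi) in cfg.covariate_model.items():
        out[name] = float(np.clip(icpt + slope * severity + rng.normal(0.0, noise), lo, hi))
    return out


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort (subjects, curves, phantoms, truth)."""
    config.validate()
    used_seed = config.seed if seed is None else int(seed)
    root = np.random.SeedSequence(used_seed)
    rng = np.random.default_rng(root)

    t = config.time_grid
    aif = generate_aif(t, config.dose_mmol_per_kg, config.aif_shape)
    ge = config.group_effects

    subjects: list[Subject] = []
    severity_map: dict[str, float] = {}
    ctcs: list[CTC] = []
    truth: dict[str, dict] = {}
    slices: dict[str, dict[str, SliceSet]] = {}

    for group in GROUPS:
        n_sub = config.n_subjects.get(group, 0)
        for i in range(n_sub):
            sid = f"{group}_{i + 1:03d}"
            s = float(rng.normal(config.severity_mean[group], config.severity_sd[group]))
            cov = _sample_covariates(rng, config, s)
            subj = Subject(
                subject_id=sid, group=group,
                AHI=cov["AHI"], ODI=cov["ODI"], LSaO2=cov["LSaO2"], BMI=cov["BMI"],
                MMSE=cov["MMSE"], MoCA=cov["MoCA"], PSQI=cov["PSQI"], ESS=cov["ESS"],
                sex="F" if rng.random() < 0.44 else "M",
                age=float(np.clip(rng.normal(52.0, 11.0), 30.0, 80.0)),
            )
            subjects.append(subj)
            severity_map[sid] = s

            # centred severity modulation: group means stay at the multipliers
            s_centered = s - config.severity_mean[group]
            peak_mod = float(np.exp(ge.peak_severity_coupling * s_centered))
            washout_mod = float(np.exp(-ge.washout_severity_coupling * s_centered))

            n_curves = _truncated_poisson(rng, config.curves_per_subject_mean[group])
            is_type1 = rng.random(n_curves) < config.type1_fraction[group]
            kt = np.empty(n_curves)
            kp = np.empty(n_curves)
            vp = np.empty(n_curves)
            for j in range(n_curves):
                if is_type1[j]:
                    pf = peak_mod * (ge.typeI_peak_mult if group == "OSA_pre" else 1.0)
                    wf = washout_mod * (ge.typeI_washout_mult if group == "OSA_pre" else 1.0)
                    kt[j], kp[j], vp[j] = _draw_params(rng, config.typeI_params, pf, wf)
                else:
                    pf = peak_mod * (ge.typeII_peak_mult if group == "OSA_post" else 1.0)
                    kt[j], kp[j], vp[j] = _draw_params(
                        rng, config.typeII_params, pf, washout_mod
                    )
            clean = tofts_forward_batch(kt, kp, vp, aif)
            noise = (
                rng.normal(0.0, config.noise_sd, size=clean.shape)
                if config.noise_sd > 0 else 0.0
            )
            noisy = clean + noise
            for j in range(n_curves):
                roi_id = f"{sid}_c{j + 1:02d}"
                ctcs.append(CTC(subject_id=sid, roi_id=roi_id, t=t, C=noisy[j]))
                truth[roi_id] = {
                    "subject_id": sid,
                    "type": "I" if is_type1[j] else "II",
                    "params": {"Ktrans": float(kt[j]), "kep": float(kp[j]),
                               "vp": float(vp[j])},
                }

            if config.include_slices:
                slices[sid] = generate_slice_masks(config, subj, rng, severity=s)

    return SyntheticCohort(
        config=config, seed=used_seed, subjects=subjects, severity=severity_map,
        aif=aif, ctcs=ctcs, truth=truth, slices=slices,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 write_nifti: bool = True) -> None:
    """Write subjects.csv, ctcs.csv, truth.json and NIfTI slices + masks."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects_frame().to_csv(out / "subjects.csv", index=False)
    cohort.ctc_frame().to_csv(out / "ctcs.csv", index=False)
    truth = {
        "seed": cohort.seed,
        "severity": cohort.severity,
        "curves": cohort.truth,
        "true_areas_mm2": {
            sid: {lvl: ss.true_areas_mm2 for lvl, ss in levels.items()}
            for sid, levels in cohort.slices.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    pd.DataFrame({"t_seconds": cohort.aif.t, "Cp_mM": cohort.aif.Cp}).to_csv(
        out / "aif.csv", index=False
    )
    if write_nifti and cohort.slices:
        import nibabel as nib

        nif_dir = out / "slices"
        nif_dir.mkdir(exist_ok=True)
        for sid, levels in cohort.slices.items():
            for lvl, ss in levels.items():
                affine = np.diag([*ss.image.pixel_spacing, 1.0, 1.0])
                nib.save(
                    nib.Nifti1Image(ss.image.pixels[..., None].astype(np.float32), affine),
                    nif_dir / f"{sid}_{lvl}.nii",
                )
                for label, mask in ss.masks.items():
                    nib.save(
                        nib.Nifti1Image(mask.pixels[..., None].astype(np.uint8), affine),
                        nif_dir / f"{sid}_{lvl}_{label}_mask.nii",
                    )
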