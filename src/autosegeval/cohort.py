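"""Synthetic multi-observer contour cohort generator.

Emulates the design of a two-arm imaging-system comparison study: each of
``n_patients`` patients is scanned once on each of two CBCT systems
(high-performance, conventional), five pelvic organs are autosegmented per
scan, and each of ``n_observers`` observers independently corrects every
contour, yielding ``n_patients * 2 * n_organs * n_observers`` delineation
records (600 at the default 20 x 2 x 5 x 3 design), plus per-delineation
correction times and 1-5 confidence scores.

Geometry: the ground-truth organ is a per-organ superellipsoid with
patient-specific size/position jitter; the AI contour is the truth deformed
by a smooth random displacement field; the observer-corrected contour is the
truth perturbed by a smaller observer-specific residual field (the AI contour
fully pulled back to truth, then observer-perturbed). Displacement magnitudes
are chosen through a per-organ calibration curve so that the induced DSC
approximately follows the crossed linear model

    y_ijk = beta0 + beta1 * x_k + u_i + v_j + eps_ijk,

with x_k = 0 for the high-performance arm and 1 for the conventional arm
(so a negative beta1 on DSC means the conventional arm is worse), u_i patient
intercepts, v_j observer intercepts. HD95 is induced by the same deformation.

For statistical unit tests :func:`generate_metric_table` simulates responses
directly from that linear model, bypassing geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .masks import BinaryMask, signed_distance, smooth_displacement_field, superellipsoid, warp_sdf

HIGH_PERFORMANCE = "high_performance"
CONVENTIONAL = "conventional"
ORGANS = ("prostate", "seminal_vesicles", "bladder", "rectum", "bowel")

# Canonical organ geometry: crop extent (mm), superellipsoid semiaxes (mm),
# exponent, and truth-centre position within the crop (mm). Bladder gets an
# elongated crop so the outlier scenario can realise a >60 mm displacement.
_ORGAN_GEOMETRY = {
    "prostate": {"crop_mm": (80, 80, 80), "semiaxes_mm": (22, 20, 18), "exponent": 2.5,
                 "center_frac": (0.5, 0.5, 0.5)},
    "seminal_vesicles": {"crop_mm": (80, 80, 80), "semiaxes_mm": (26, 13, 10), "exponent": 2.0,
                         "center_frac": (0.5, 0.5, 0.5)},
    "bladder": {"crop_mm": (160, 96, 96), "semiaxes_mm": (27, 26, 24), "exponent": 3.0,
                "center_frac": (0.25, 0.5, 0.5)},
    "rectum": {"crop_mm": (80, 80, 120), "semiaxes_mm": (13, 13, 42), "exponent": 2.2,
               "center_frac": (0.5, 0.5, 0.5)},
    "bowel": {"crop_mm": (112, 112, 96), "semiaxes_mm": (40, 34, 22), "exponent": 1.8,
              "center_frac": (0.5, 0.5, 0.5)},
}

_FIELD_CORRELATION_MM = 12.0  # correlation length of deformation fields
_FIT_MARGIN_MM = 8.0          # clearance required between organ and crop faces


def _default_beta0_dsc():
    return {"prostate": 0.86, "seminal_vesicles": 0.71, "bladder": 0.95,
            "rectum": 0.89, "bowel": 0.86}


def _default_beta1_dsc():
    # conventional minus high-performance on the DSC scale
    return {"prostate": -0.01, "seminal_vesicles": 0.00, "bladder": -0.04,
            "rectum": 0.00, "bowel": -0.03}


def _default_beta0_hd95():
    return {"prostate": 5.03, "seminal_vesicles": 6.14, "bladder": 4.53,
            "rectum": 8.25, "bowel": 11.33}


def _default_beta1_hd95():
    return {"prostate": 0.35, "seminal_vesicles": 0.63, "bladder": 1.95,
            "rectum": 0.13, "bowel": 0.68}


def _default_correction_time_model():
    # arm-level total (five organs) mean/SD in seconds; per-organ split of the mean
    return {
        "total_mean_s": {HIGH_PERFORMANCE: 663.0, CONVENTIONAL: 672.0},
        "total_sd_s": {HIGH_PERFORMANCE: 197.0, CONVENTIONAL: 190.0},
        "organ_fraction": {"prostate": 0.28, "seminal_vesicles": 0.22, "bladder": 0.14,
                           "rectum": 0.18, "bowel": 0.18},
        "record_lognorm_sigma": 0.25,
    }


def _discrete_confidence(mean: float, width: float = 0.7) -> list[float]:
    """Categorical distribution over scores 1..5 concentrated around ``mean``."""
    k = np.arange(1, 6)
    p = np.exp(-0.5 * ((k - mean) / width) ** 2)
    p = p / p.sum()
    return [float(x) for x in p]


def _default_confidence_model():
    means = {
        "prostate": {HIGH_PERFORMANCE: 4.5, CONVENTIONAL: 3.5},
        "seminal_vesicles": {HIGH_PERFORMANCE: 4.3, CONVENTIONAL: 3.5},
        "bladder": {HIGH_PERFORMANCE: 4.9, CONVENTIONAL: 4.5},
        "rectum": {HIGH_PERFORMANCE: 4.8, CONVENTIONAL: 4.3},
        "bowel": {HIGH_PERFORMANCE: 4.6, CONVENTIONAL: 4.4},
    }
    return {organ: {arm: _discrete_confidence(m) for arm, m in arms.items()}
            for organ, arms in means.items()}


@dataclass
class CohortConfig:
    """Full specification of a synthetic study; the defaults are the study
    conditions (20 patients, 2 systems, 3 observers, 5 organs, 96 voxel grid
    at 2 mm isotropic spacing)."""

    n_patients: int = 20
    n_observers: int = 3
    imaging_systems: tuple[str, str] = (HIGH_PERFORMANCE, CONVENTIONAL)
    organs: tuple[str, ...] = ORGANS
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    beta0_dsc: dict = field(default_factory=_default_beta0_dsc)
    beta1_dsc: dict = field(default_factory=_default_beta1_dsc)
    beta0_hd95: dict = field(default_factory=_default_beta0_hd95)
    beta1_hd95: dict = field(default_factory=_default_beta1_hd95)
    sigma2_patient: float = 0.0050
    sigma2_observer: float = 0.0007
    sigma2_residual: float = 0.0043
    deformation_scale: float = 1.0
    outlier_patient: int | None = None
    exclude_bowel_patient: int | None = None
    correction_time_model: dict = field(default_factory=_default_correction_time_model)
    confidence_model: dict = field(default_factory=_default_confidence_model)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if len(self.imaging_systems) != 2:
            raise ValueError("exactly two imaging systems are required")
        for s2 in (self.sigma2_patient, self.sigma2_observer, self.sigma2_residual):
            if s2 < 0:
                raise ValueError("variance components must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be strictly positive")
        if self.deformation_scale < 0:
            raise ValueError("deformation_scale must be >= 0")
        for organ in self.organs:
            if organ not in _ORGAN_GEOMETRY:
                raise ValueError(f"unknown organ '{organ}'")
            for name, table in (("beta0_dsc", self.beta0_dsc), ("beta1_dsc", self.beta1_dsc),
                                ("beta0_hd95", self.beta0_hd95), ("beta1_hd95", self.beta1_hd95)):
                if organ not in table:
                    raise ValueError(f"{name} missing entry for organ '{organ}'")
            for arm in self.imaging_systems:
                probs = self.confidence_model[organ][arm]
                if len(probs) != 5 or abs(sum(probs) - 1.0) > 1e-8 or min(probs) < 0:
                    raise ValueError(
                        f"confidence distribution for ({organ}, {arm}) must be 5 "
                        "non-negative probabilities summing to 1")
        if self.outlier_patient is not None and not (0 <= self.outlier_patient < self.n_patients):
            raise ValueError("outlier_patient index out of range")
        if self.outlier_patient is not None and "bladder" not in self.organs:
            raise ValueError("outlier scenario requires the bladder organ")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["imaging_systems"] = list(self.imaging_systems)
        d["organs"] = list(self.organs)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing_mm"] = list(self.spacing_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("imaging_systems", "organs", "grid_shape", "spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class DelineationRecord:
    """One observer's corrected contour for one (patient, system, organ)."""

    patient_id: str
    observer_id: str
    imaging_system: str
    organ: str
    truth_mask: BinaryMask | None
    ai_mask: BinaryMask | None
    corrected_mask: BinaryMask | None
    correction_time_s: float
    confidence: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing:
            if not (1 <= int(self.confidence) <= 5):
                raise ValueError("confidence must be an integer in [1, 5]")
            if self.correction_time_s < 0:
                raise ValueError("correction_time_s must be >= 0")
            masks = [self.truth_mask, self.ai_mask, self.corrected_mask]
            if any(m is None for m in masks):
                raise ValueError("non-missing records require all three masks")
            if not (self.truth_mask.same_grid(self.ai_mask)
                    and self.truth_mask.same_grid(self.corrected_mask)):
                raise ValueError("truth, AI and corrected masks must share grid and spacing")


# ---------------------------------------------------------------------------
# organ layout on the study grid
# ---------------------------------------------------------------------------

def _organ_layout(config: CohortConfig) -> dict:
    """Resolve each organ's sub-grid (crop shape in voxels, origin in mm) and
    check the study grid can contain it; failures name the organ."""
    spacing = np.asarray(config.spacing_mm)
    grid_mm = spacing * np.asarray(config.grid_shape)
    layout = {}
    for organ in config.organs:
        geo = _ORGAN_GEOMETRY[organ]
        crop_mm = np.asarray(geo["crop_mm"], dtype=float)
        crop_vox = np.ceil(crop_mm / spacing).astype(int)
        if np.any(crop_vox > np.asarray(config.grid_shape)):
            raise ValueError(
                f"grid too small to contain organ '{organ}': needs "
                f"{crop_mm.tolist()} mm, grid is {grid_mm.tolist()} mm")
        semi = np.asarray(geo["semiaxes_mm"])
        center = np.asarray(geo["center_frac"]) * crop_vox * spacing
        lo = center - 1.1 * semi - _FIT_MARGIN_MM
        hi = center + 1.1 * semi + _FIT_MARGIN_MM
        if np.any(lo < 0) or np.any(hi > crop_vox * spacing):
            raise ValueError(
                f"grid too small to contain organ '{organ}' at the requested size")
        # crop placed at the low corner of the study grid (origin 0); organs are
        # analysed independently so overlap of crops is irrelevant
        layout[organ] = {
            "shape": tuple(int(v) for v in crop_vox),
            "origin_mm": (0.0, 0.0, 0.0),
            "center_mm": center,
            "semiaxes_mm": semi,
            "exponent": geo["exponent"],
        }
    return layout


def _truth_mask(organ: str, layout: dict, spacing, size_jitter, center_jitter_mm) -> BinaryMask:
    info = layout[organ]
    return superellipsoid(
        info["shape"], spacing,
        center_mm=info["center_mm"] + center_jitter_mm,
        semiaxes_mm=info["semiaxes_mm"] * size_jitter,
        exponent=info["exponent"],
        origin_mm=info["origin_mm"],
    )


# ---------------------------------------------------------------------------
# displacement-magnitude calibration (magnitude -> expected DSC / HD95)
# ---------------------------------------------------------------------------

_CAL_MAGNITUDES = (0.75, 1.5, 3.0, 6.0, 12.0)
_calibration_cache: dict = {}


def _calibration(organ: str, config: CohortConfig) -> dict:
    """Empirical monotone lookup from displacement RMS (mm) to expected DSC and
    HD95 for this organ's canonical shape, regenerated under a fixed seed."""
    from .metrics import dice, hd95 as hd95_metric

    key = (organ, tuple(config.spacing_mm))
    if key in _calibration_cache:
        return _calibration_cache[key]
    layout = _organ_layout(config)
    truth = _truth_mask(organ, layout, config.spacing_mm, np.ones(3), np.zeros(3))
    sdf = signed_distance(truth)
    rng = np.random.default_rng(np.random.SeedSequence([7771, hash(organ) % (2 ** 31)]))
    dscs, hds = [1.0], [0.0]
    for m in _CAL_MAGNITUDES:
        dv, hv = [], []
        for _ in range(3):
            fld = smooth_displacement_field(truth.shape, config.spacing_mm, m,
                                            _FIELD_CORRELATION_MM, rng)
            warped = warp_sdf(sdf, truth, fld)
            dv.append(dice(truth, warped))
            hv.append(hd95_metric(truth, warped))
        dscs.append(float(np.mean(dv)))
        hds.append(float(np.mean(hv)))
    mags = np.array((0.0,) + _CAL_MAGNITUDES)
    dscs = np.minimum.accumulate(np.array(dscs))  # enforce monotone decrease
    cal = {"magnitude_mm": mags, "dsc": dscs, "hd95_mm": np.array(hds)}
    _calibration_cache[key] = cal
    return cal


def _magnitude_for_dsc(target_dsc: float, cal: dict) -> float:
    """Invert the calibration curve; targets are clipped to the curve's range."""
    d = cal["dsc"][::-1]
    m = cal["magnitude_mm"][::-1]
    t = float(np.clip(target_dsc, d[0], d[-1]))
    return float(np.interp(t, d, m))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _patient_ids(n: int) -> list[str]:
    return [f"P{i:02d}" for i in range(n)]


def _observer_ids(n: int) -> list[str]:
    return [f"O{j + 1}" for j in range(n)]


def generate_cohort(config: CohortConfig) -> list[DelineationRecord]:
    """Generate the full synthetic study; same config (incl. seed) gives
    bit-identical masks and metadata."""
    config.validate()
    layout = _organ_layout(config)
    spacing = config.spacing_mm
    ss = np.random.SeedSequence([int(config.seed), 20241209])
    rng_anat, rng_eff, rng_fields, rng_time, rng_conf = (
        np.random.default_rng(c) for c in ss.spawn(5))

    a, b = config.n_patients, config.n_observers
    organs = config.organs
    pids, oids = _patient_ids(a), _observer_ids(b)

    # anatomy jitter, drawn in a fixed order
    size_jit = {(i, org): rng_anat.uniform(0.92, 1.08, size=3)
                for i in range(a) for org in organs}
    cent_jit = {(i, org): rng_anat.uniform(-4.0, 4.0, size=3)
                for i in range(a) for org in organs}

    # linear-model effects per organ (DSC scale)
    u = {org: rng_eff.normal(0.0, np.sqrt(config.sigma2_patient), size=a) for org in organs}
    v = {org: rng_eff.normal(0.0, np.sqrt(config.sigma2_observer), size=b) for org in organs}
    eps = {org: rng_eff.normal(0.0, np.sqrt(config.sigma2_residual), size=(a, 2, b))
           for org in organs}

    # independent child seeds for every displacement field
    field_seeds = rng_fields.integers(0, 2 ** 31, size=(a, 2, len(organs), b + 1))

    tm = config.correction_time_model
    sd_frac = {arm: tm["total_sd_s"][arm] / tm["total_mean_s"][arm]
               for arm in config.imaging_systems}
    pat_sigma = {arm: float(np.sqrt(np.log(1.0 + sd_frac[arm] ** 2)))
                 for arm in config.imaging_systems}
    pat_factor = {i: rng_time.standard_normal() for i in range(a)}
    rec_sigma = tm["record_lognorm_sigma"]

    records: list[DelineationRecord] = []
    truths: dict = {}
    sdfs: dict = {}
    for i in range(a):
        for org in organs:
            t = _truth_mask(org, layout, spacing, size_jit[(i, org)], cent_jit[(i, org)])
            truths[(i, org)] = t
            sdfs[(i, org)] = signed_distance(t)

    for i in range(a):
        for k, arm in enumerate(config.imaging_systems):
            x = 0.0 if arm == HIGH_PERFORMANCE else 1.0
            for g, org in enumerate(organs):
                truth = truths[(i, org)]
                sdf = sdfs[(i, org)]
                cal = _calibration(org, config) if config.deformation_scale > 0 else None
                targets = (config.beta0_dsc[org] + config.beta1_dsc[org] * x
                           + u[org][i] + v[org] + eps[org][i, k])
                if config.deformation_scale > 0:
                    m_total = np.array([
                        config.deformation_scale * _magnitude_for_dsc(t, cal)
                        for t in targets])
                else:
                    m_total = np.zeros(b)
                m_ai = 0.9 * float(m_total.min())
                if m_ai > 0:
                    fld = smooth_displacement_field(
                        truth.shape, spacing, m_ai, _FIELD_CORRELATION_MM,
                        np.random.default_rng(int(field_seeds[i, k, g, 0])))
                    ai = warp_sdf(sdf, truth, fld)
                else:
                    ai = truth
                for j in range(b):
                    m_obs = float(np.sqrt(max(m_total[j] ** 2 - m_ai ** 2, 0.0)))
                    if m_obs > 1e-9:
                        fld = smooth_displacement_field(
                            truth.shape, spacing, m_obs, _FIELD_CORRELATION_MM,
                            np.random.default_rng(int(field_seeds[i, k, g, j + 1])))
                        corrected = warp_sdf(sdf, truth, fld)
                    else:
                        corrected = truth
                    mean_t = tm["total_mean_s"][arm] * tm["organ_fraction"][org]
                    t_s = mean_t * np.exp(pat_factor[i] * pat_sigma[arm]
                                          - pat_sigma[arm] ** 2 / 2.0) \
                        * np.exp(rng_time.standard_normal() * rec_sigma - rec_sigma ** 2 / 2.0)
                    probs = config.confidence_model[org][arm]
                    conf = int(rng_conf.choice(np.arange(1, 6), p=probs))
                    missing = (config.exclude_bowel_patient is not None
                               and org == "bowel" and i == config.exclude_bowel_patient)
                    records.append(DelineationRecord(
                        patient_id=pids[i], observer_id=oids[j], imaging_system=arm,
                        organ=org,
                        truth_mask=None if missing else truth,
                        ai_mask=None if missing else ai,
                        corrected_mask=None if missing else corrected,
                        correction_time_s=float(t_s), confidence=conf, missing=missing))

    if config.outlier_patient is not None:
        records = apply_outlier_scenario(records, config.outlier_patient)
    return records


def apply_outlier_scenario(records: list[DelineationRecord],
                           patient_index: int) -> list[DelineationRecord]:
    """Replace the flagged patient's conventional-arm bladder AI contour with a
    grossly displaced, shrunken one (DSC < 0.2, HD95 > 60 mm vs the corrected
    contour); the high-performance arm is untouched."""
    pid = f"P{patient_index:02d}"
    targets = [r for r in records
               if r.patient_id == pid and r.imaging_system == CONVENTIONAL
               and r.organ == "bladder" and not r.missing]
    if not targets:
        raise ValueError(f"no conventional-arm bladder records for patient index {patient_index}")
    truth = targets[0].truth_mask
    spacing = np.asarray(truth.spacing_mm)
    idx = np.argwhere(truth.voxels)
    com_mm = idx.mean(axis=0) * spacing
    half_extent = 0.5 * (idx.max(axis=0) - idx.min(axis=0)) * spacing
    crop_mm = np.asarray(truth.shape) * spacing
    semi_out = np.maximum(0.4 * half_extent, 6.0)
    shift = 100.0
    axis = int(np.argmax(crop_mm))
    center = com_mm.copy()
    if com_mm[axis] + shift + semi_out[axis] + 4.0 <= crop_mm[axis]:
        center[axis] += shift
    elif com_mm[axis] - shift - semi_out[axis] - 4.0 >= 0.0:
        center[axis] -= shift
    else:
        raise ValueError(
            "grid too small to realize the 60 mm outlier separation for organ 'bladder'")
    outlier_ai = superellipsoid(truth.shape, truth.spacing_mm, center, semi_out,
                                exponent=3.0, origin_mm=truth.origin_mm)
    out = []
    for r in records:
        if (r.patient_id == pid and r.imaging_system == CONVENTIONAL
                and r.organ == "bladder" and not r.missing):
            out.append(dataclasses.replace(r, ai_mask=outlier_ai))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# direct simulation from the crossed linear model
# ---------------------------------------------------------------------------

def generate_metric_table(params: dict, seed: int, response: str = "value",
                          organ: str = "simulated") -> pd.DataFrame:
    """Simulate a balanced complete metric table straight from the crossed
    random-intercepts model, bypassing geometry.

    ``params`` must contain beta0, beta1, sigma2_patient, sigma2_observer,
    sigma2_residual, n_patients, n_observers. The imaging-system covariate is
    coded 0 for the high-performance arm and 1 for the conventional arm.
    """
    required = {"beta0", "beta1", "sigma2_patient", "sigma2_observer",
                "sigma2_residual", "n_patients", "n_observers"}
    missing = required - set(params)
    if missing:
        raise ValueError(f"missing params: {sorted(missing)}")
    for key in ("sigma2_patient", "sigma2_observer", "sigma2_residual"):
        if params[key] < 0:
            raise ValueError(f"{key} must be >= 0")
    a, b = int(params["n_patients"]), int(params["n_observers"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 424243]))
    u = rng.normal(0.0, np.sqrt(params["sigma2_patient"]), size=a)
    v = rng.normal(0.0, np.sqrt(params["sigma2_observer"]), size=b)
    e = rng.normal(0.0, np.sqrt(params["sigma2_residual"]), size=(a, 2, b))
    x = np.array([0.0, 1.0])
    y = (params["beta0"] + params["beta1"] * x[None, :, None]
         + u[:, None, None] + v[None, None, :] + e)
    pids = np.array([f"P{i:02d}" for i in range(a)])
    oids = np.array([f"O{j + 1}" for j in range(b)])
    arms = np.array([HIGH_PERFORMANCE, CONVENTIONAL])
    ii, kk, jj = np.meshgrid(np.arange(a), np.arange(2), np.arange(b), indexing="ij")
    return pd.DataFrame({
        "patient_id": pids[ii.ravel()], "observer_id": oids[jj.ravel()],
        "imaging_system": arms[kk.ravel()], "organ": organ,
        response: y.ravel()})


def records_to_frame(records: list[DelineationRecord]) -> pd.DataFrame:
    """Tabulate record metadata (no masks): one row per delineation."""
    return pd.DataFrame([
        {"patient_id": r.patient_id, "observer_id": r.observer_id,
         "imaging_system": r.imaging_system, "organ": r.organ,
         "correction_time_s": r.correction_time_s, "confidence": r.confidence,
         "missing": r.missing}
        for r in records])


def n_scan_units(records: list[DelineationRecord]) -> int:
    return len({(r.patient_id, r.imaging_system) for r in records})


# ---------------------------------------------------------------------------
# on-disk representation: NIfTI masks + CSV metadata
# ---------------------------------------------------------------------------

def write_cohort(records: list[DelineationRecord], out_dir) -> None:
    """Write masks as NIfTI (one file per patient/system/organ/role, shared
    truth/AI masks written once) and metadata as CSV."""
    import pathlib

    from .masks import save_nifti

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = set()
    for r in records:
        if r.missing:
            continue
        key = (r.patient_id, r.imaging_system, r.organ)
        stem = f"{r.patient_id}_{r.imaging_system}_{r.organ}"
        if key not in written:
            save_nifti(r.truth_mask, out / f"{stem}_truth.nii.gz")
            save_nifti(r.ai_mask, out / f"{stem}_ai.nii.gz")
            written.add(key)
        save_nifti(r.corrected_mask, out / f"{stem}_{r.observer_id}_corrected.nii.gz")
    records_to_frame(records).to_csv(out / "metadata.csv", index=False)


def read_cohort(in_dir) -> list[DelineationRecord]:
    """Reconstruct delineation records from a directory written by
    :func:`write_cohort`."""
    import pathlib

    from .masks import load_nifti

    src = pathlib.Path(in_dir)
    meta = pd.read_csv(src / "metadata.csv")
    cache: dict = {}

    def _load(name):
        if name not in cache:
            cache[name] = load_nifti(src / name)
        return cache[name]

    records = []
    for _, row in meta.iterrows():
        stem = f"{row.patient_id}_{row.imaging_system}_{row.organ}"
        missing = bool(row.missing)
        records.append(DelineationRecord(
            patient_id=row.patient_id, observer_id=row.observer_id,
            imaging_system=row.imaging_system, organ=row.organ,
            truth_mask=None if missing else _load(f"{stem}_truth.nii.gz"),
            ai_mask=None if missing else _load(f"{stem}_ai.nii.gz"),
            corrected_mask=None if missing
            else _load(f"{stem}_{row.observer_id}_corrected.nii.gz"),
            correction_time_s=float(row.correction_time_s),
            confidence=int(row.confidence), missing=missing))
    return records
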