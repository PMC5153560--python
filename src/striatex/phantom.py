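"""Synthetic DAT-SPECT-like striatal phantom cohorts.

Each phantom is an ellipsoidal striatum (bilateral caudate and putamen)
plus an occipital reference slab embedded in nonspecific background.
Disease state is a latent severity in [0, 1] that drives

* mean dopaminergic loss in the putamen (response x1.5 vs the latent
  scale, with an extra asymmetry factor on the more affected side),
* a rostrocaudal uptake gradient within each structure,
* a severity-scaled multiplicative "patchy loss" random field
  emulating the spatially uneven terminal degeneration the texture
  analysis is designed to detect, and
* the clinical scores (UPDRS-III, disease durations, MoCA) through
  noisy linear links.

The caudate is built with a mean-preserving (centred) gradient and only
a weak explicit mean-loss term, so that its mean uptake is nearly
severity-independent while its within-ROI heterogeneity carries the
severity signal — the qualitative regime the downstream statistics are
validated against. Technical noise is additive Gaussian before the
6 mm FWHM post-reconstruction smoothing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .volume import (
    RegionMaskSet,
    STRIATAL_REGIONS,
    Volume,
    _FWHM_TO_SIGMA,
    gaussian_smooth,
    read_mask_set,
    read_volume,
    write_mask_set,
    write_volume,
)
from scipy import ndimage
from scipy.special import ndtr as _norm_cdf

__all__ = [
    "PhantomParams",
    "ClinicalRecord",
    "Cohort",
    "make_masks",
    "make_affine",
    "simulate_subject",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "clinical_frame",
]

# ellipsoid semi-axes and centres in world mm (grid centre at origin);
# caudate ~1.4 cm^3, putamen ~4.0 cm^3 at any spacing
_GEOMETRY = {
    "caudate": {"semi_axes": (4.5, 9.0, 8.5), "center": (11.0, 8.0, 6.0)},
    "putamen": {"semi_axes": (6.0, 13.0, 12.0), "center": (26.0, 2.0, 0.0)},
}
# posterior slab used as the nonspecific reference region
_OCCIPITAL_BOX = {"x": (-30.0, 30.0), "y": (-44.0, -30.0), "z": (-14.0, 14.0)}


@dataclass
class PhantomParams:
    """Generator settings; defaults define the reference study conditions.

    The severity-driven heterogeneity has two components applied within
    each striatal mask after the reconstruction-style smoothing (they
    emulate sub-resolution uneven loss that in real images survives as
    voxel-scale texture):

    * ``patchiness`` — amplitude of a fine-scale (``patch_fwhm_mm``)
      multiplicative jitter whose local amplitude tapers to zero at
      both ends of the region's intensity envelope, so the in-mask
      min/max (and hence the quantization range) are preserved;
    * a nested "lesion territory" covering a fraction
      ``lesion_fraction_max * severity**texture_onset_exponent`` of the
      field of view (threshold on a smooth ``lesion_fwhm_mm`` random
      field), inside which uptake is remapped toward the region floor
      with fine-scale structure (``lesion_floor`` keeps it off the
      exact floor).
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 48)
    spacing_mm: float = 2.0
    background_level: float = 25.0
    reference_level: float = 30.0
    striatal_base: float = 90.0
    gradient_steepness: float = 0.04  # fractional loss per mm from rostral pole
    asymmetry: float = 0.3
    noise_sd: float = 6.0
    fwhm_mm: float = 6.0
    patchiness: float = 1.0  # envelope-tapered fine jitter amplitude
    patch_fwhm_mm: float = 1.5
    lesion_fraction_max: float = 0.35
    lesion_fwhm_mm: float = 8.0
    lesion_floor: float = 0.15
    texture_onset_exponent: float = 2.0
    subject_cv: float = 0.15  # between-subject striatal binding variability
    global_cv: float = 0.10  # whole-volume scanner sensitivity factor
    caudate_mean_response: float = 0.02
    putamen_gain: float = 1.5
    caudate_side_texture_gain: float = 0.4
    randomize_side: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.striatal_base > self.background_level > 0):
            raise ValueError("need striatal_base > background_level > 0")
        if self.reference_level <= 0:
            raise ValueError("reference_level must be positive")
        for name in ("gradient_steepness", "noise_sd", "patchiness",
                     "subject_cv", "global_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.asymmetry < 1):
            raise ValueError("asymmetry must lie in [0, 1)")
        if not (0 <= self.lesion_fraction_max < 1):
            raise ValueError("lesion_fraction_max must lie in [0, 1)")
        if self.fwhm_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("fwhm_mm and spacing_mm must be positive")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class ClinicalRecord:
    """Per-subject clinical scores plus the generator's latent truth."""

    subject_id: str
    group: str
    updrs3: float
    dd_diag_months: float
    dd_sympt_months: float
    moca: float
    age: float
    latent_severity: float
    more_affected_side: str = "L"

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError(f"group must be PD or HC, got {self.group!r}")
        if not (0.0 <= self.latent_severity <= 1.0):
            raise ValueError("latent_severity must lie in [0, 1]")
        if self.group == "HC" and self.latent_severity != 0.0:
            raise ValueError("HC records must have latent_severity = 0")
        if not (0.0 <= self.moca <= 30.0):
            raise ValueError("moca must lie in [0, 30]")
        if self.updrs3 < 0 or self.dd_diag_months < 0 or self.dd_sympt_months < 0:
            raise ValueError("scores and durations must be nonnegative")
        if self.group == "PD" and self.dd_sympt_months < self.dd_diag_months:
            raise ValueError("dd_sympt_months must be >= dd_diag_months for PD")
        if self.more_affected_side not in ("L", "R"):
            raise ValueError("more_affected_side must be 'L' or 'R'")


@dataclass
class Cohort:
    """A simulated cohort: volumes, shared masks, clinical records, truth."""

    volumes: List[Volume]
    masks: RegionMaskSet
    records: List[ClinicalRecord]
    truth: List[Dict[str, float]]
    params: PhantomParams


def make_affine(params: PhantomParams) -> np.ndarray:
    """Centred isotropic affine: world origin at the grid centre."""
    aff = np.diag([params.spacing_mm] * 3 + [1.0])
    shape = np.asarray(params.grid_shape, dtype=float)
    aff[:3, 3] = -params.spacing_mm * (shape - 1) / 2.0
    return aff


def _world_grids(params: PhantomParams):
    aff = make_affine(params)
    idx = np.indices(params.grid_shape, dtype=float)
    coords = [
        aff[k, k] * idx[k] + aff[k, 3] for k in range(3)
    ]  # diagonal affine: axes independent
    return coords


def make_masks(params: PhantomParams) -> RegionMaskSet:
    """Mirrored caudate/putamen ellipsoid pairs plus an occipital slab.

    Deterministic given the parameters; raises if a region would leave
    the grid or regions would overlap.
    """
    X, Y, Z = _world_grids(params)
    half_extent = np.array(params.grid_shape) * params.spacing_mm / 2.0
    masks: Dict[str, np.ndarray] = {}
    for struct, geo in _GEOMETRY.items():
        a, b, c = geo["semi_axes"]
        cx, cy, cz = geo["center"]
        for side, sx in (("L", -1.0), ("R", 1.0)):
            lo = np.array([sx * cx - a, cy - b, cz - c])
            hi = np.array([sx * cx + a, cy + b, cz + c])
            if np.any(np.abs(lo) > half_extent) or np.any(np.abs(hi) > half_extent):
                raise ValueError(
                    f"region {struct}_{side} exceeds the grid "
                    f"(extent {half_extent}, needs [{lo}, {hi}])"
                )
            masks[f"{struct}_{side}"] = (
                ((X - sx * cx) / a) ** 2 + ((Y - cy) / b) ** 2 + ((Z - cz) / c) ** 2
            ) <= 1.0
    box = _OCCIPITAL_BOX
    occ = (
        (X >= box["x"][0]) & (X <= box["x"][1])
        & (Y >= box["y"][0]) & (Y <= box["y"][1])
        & (Z >= box["z"][0]) & (Z <= box["z"][1])
    )
    if np.abs(np.array([v for pair in box.values() for v in pair])).max() > half_extent.max():
        raise ValueError("occipital slab exceeds the grid")
    masks["occipital"] = occ
    for name in STRIATAL_REGIONS:
        if occ[masks[name]].any():
            raise ValueError(f"occipital slab overlaps {name}")
    return RegionMaskSet(masks)  # validates striatal disjointness / emptiness


def _rostrocaudal_gradient(params: PhantomParams, mask: np.ndarray, Y: np.ndarray):
    """Unit ramp g in [0, 1]: 0 at the rostral (anterior, +y) pole,
    gradient_steepness per mm toward the caudal pole, clipped at 1."""
    y = Y[mask]
    g = np.clip(params.gradient_steepness * (y.max() - y), 0.0, 1.0)
    return g


def _smooth_unit_field(shape, fwhm_mm: float, spacing_mm: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian random field with the given correlation FWHM."""
    white = rng.standard_normal(shape)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / spacing_mm
    field_ = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def simulate_subject(
    params: PhantomParams,
    record: ClinicalRecord,
    masks: Optional[RegionMaskSet] = None,
    rng: Optional[np.random.Generator] = None,
    return_truth: bool = False,
):
    """Render one subject's emission volume.

    Deterministic stage (before noise and smoothing), with severity
    s in [0, 1], rostrocaudal unit ramp g and e the texture-onset
    exponent:

    * putamen:  base_i * side * (1 - s_p * g(x)), side = 1 -
      asymmetry*s on the more affected side, s_p = min(1, 1.5*s);
    * caudate:  base_i * (1 - c_mean*s) * (1 - A * s**e * (g - mean(g)))
      with A = 1 + 0.4*asymmetry*s on the more affected side — a
      mean-preserving gradient plus the weak ``caudate_mean_response``
      term, so caudate mean uptake is nearly severity-flat while its
      heterogeneity carries the severity signal.

    Additive Gaussian technical noise and the isotropic ``fwhm_mm``
    smoothing follow. Severity-scaled heterogeneity (nested lesion
    territory remapped toward the region floor, plus envelope-tapered
    fine-scale jitter; see :class:`PhantomParams`) is then applied
    inside each striatal mask with the region mean re-centred, so
    region means are untouched by the texture machinery. Severity 0
    yields a symmetric, gradient- and lesion-free healthy phantom.

    ``return_truth`` additionally returns the noise-free pre-smoothing
    in-mask mean per region (the analytic model integrals).
    """
    if masks is None:
        masks = make_masks(params)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = record.latent_severity
    if not (0.0 <= s <= 1.0):
        raise ValueError("severity must lie in [0, 1]")
    e = params.texture_onset_exponent

    _, Y, _ = _world_grids(params)
    base_i = params.striatal_base * max(0.3, 1.0 + params.subject_cv * rng.standard_normal())
    global_i = max(0.3, 1.0 + params.global_cv * rng.standard_normal())
    lesion_field = _smooth_unit_field(
        params.grid_shape, params.lesion_fwhm_mm, params.spacing_mm, rng
    )
    fine_field = _smooth_unit_field(
        params.grid_shape, params.patch_fwhm_mm, params.spacing_mm, rng
    )
    fine01 = _norm_cdf(fine_field)  # rank-flat in [0, 1]: no amplitude tails

    data = np.full(params.grid_shape, params.background_level, dtype=float)
    data[masks["occipital"]] = params.reference_level

    truth: Dict[str, float] = {"occipital": params.reference_level * global_i}
    for struct in ("caudate", "putamen"):
        for side in ("L", "R"):
            name = f"{struct}_{side}"
            mask = masks[name]
            g = _rostrocaudal_gradient(params, mask, Y)
            more = side == record.more_affected_side
            if struct == "putamen":
                side_factor = 1.0 - params.asymmetry * s if more else 1.0
                s_p = min(1.0, params.putamen_gain * s)
                vals = base_i * side_factor * (1.0 - s_p * g)
            else:
                amp = 1.0 + params.caudate_side_texture_gain * params.asymmetry * s if more else 1.0
                vals = (
                    base_i * (1.0 - params.caudate_mean_response * s)
                    * (1.0 - amp * s**e * (g - g.mean()))
                )
            vals = np.clip(vals, 0.0, None)
            data[mask] = vals
            truth[name] = float(vals.mean()) * global_i

    data *= global_i
    if params.noise_sd > 0:
        data += rng.normal(0.0, params.noise_sd, size=params.grid_shape)
    vol = gaussian_smooth(Volume(data, make_affine(params)), params.fwhm_mm)

    if s > 0:
        frac = params.lesion_fraction_max * s**e
        if frac > 0:
            thr = np.quantile(lesion_field, 1.0 - frac)
            territory = lesion_field > thr
        else:
            territory = np.zeros(params.grid_shape, dtype=bool)
        d = vol.data
        for struct in ("caudate", "putamen"):
            for side in ("L", "R"):
                mask = masks[f"{struct}_{side}"]
                vm = d[mask]
                floor, ceil, mu = vm.min(), vm.max(), vm.mean()
                out = vm.copy()
                les = territory[mask]
                if les.any():
                    lf = params.lesion_floor
                    out[les] = floor + (vm[les] - floor) * (
                        lf + (1.0 - lf) * fine01[mask][les]
                    )
                more = side == record.more_affected_side
                jit = params.patchiness * s
                if struct == "caudate" and more:
                    jit *= 1.0 + params.caudate_side_texture_gain * params.asymmetry * s
                jit = min(jit, 1.0)  # taper bound keeps values inside [floor, ceil]
                u = 2.0 * fine01[mask] - 1.0
                out = out + jit * np.minimum(out - floor, ceil - out) * u
                out += mu - out.mean()  # region mean untouched by texture
                d[mask] = np.clip(out, 0.0, None)

    if return_truth:
        return vol, truth
    return vol


def _simulate_clinical(
    params: PhantomParams, n_pd: int, n_hc: int, rng: np.random.Generator
) -> List[ClinicalRecord]:
    records = []
    for i in range(n_pd):
        s = rng.uniform(0.1, 1.0)
        updrs = max(0.0, 5.0 + 45.0 * s + rng.normal(0.0, 6.0))
        dd_diag = max(0.0, 60.0 * s + rng.normal(0.0, 8.0))
        dd_sympt = dd_diag + abs(rng.normal(12.0, 6.0))
        moca = float(np.clip(28.0 - 6.0 * s + rng.normal(0.0, 1.5), 0.0, 30.0))
        age = rng.normal(61.0, 9.0)
        side = ("L", "R")[rng.integers(2)] if params.randomize_side else "L"
        records.append(
            ClinicalRecord(
                subject_id=f"PD{i + 1:03d}", group="PD", updrs3=updrs,
                dd_diag_months=dd_diag, dd_sympt_months=dd_sympt, moca=moca,
                age=float(age), latent_severity=float(s), more_affected_side=side,
            )
        )
    for i in range(n_hc):
        records.append(
            ClinicalRecord(
                subject_id=f"HC{i + 1:03d}", group="HC",
                updrs3=abs(rng.normal(1.0, 1.0)),
                dd_diag_months=0.0, dd_sympt_months=0.0,
                moca=float(np.clip(28.0 + rng.normal(0.0, 1.0), 0.0, 30.0)),
                age=float(rng.normal(61.0, 9.0)),
                latent_severity=0.0,
            )
        )
    return records


def simulate_cohort(params: PhantomParams, n_pd: int = 85, n_hc: int = 56) -> Cohort:
    """Simulate a full cohort; fully reproducible from ``params.seed``."""
    if n_pd < 0 or n_hc < 0:
        raise ValueError("cohort sizes must be nonnegative")
    seeds = np.random.SeedSequence(params.seed).spawn(n_pd + n_hc + 1)
    clin_rng = np.random.default_rng(seeds[0])
    records = _simulate_clinical(params, n_pd, n_hc, clin_rng)
    masks = make_masks(params)
    volumes, truth = [], []
    for i, rec in enumerate(records):
        vol, tr = simulate_subject(
            params, rec, masks=masks, rng=np.random.default_rng(seeds[i + 1]),
            return_truth=True,
        )
        volumes.append(vol)
        truth.append(tr)
    return Cohort(volumes=volumes, masks=masks, records=records, truth=truth,
                  params=params)


_CLINICAL_COLUMNS = [
    "subject_id", "group", "updrs3", "dd_diag_months", "dd_sympt_months",
    "moca", "age", "latent_severity", "more_affected_side",
]


def clinical_frame(records: List[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=_CLINICAL_COLUMNS)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write volumes, masks, clinical CSV and a YAML manifest; returns
    the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = make_affine(cohort.params)
    mask_paths = write_mask_set(cohort.masks, affine, out_dir / "masks")
    subjects = []
    for vol, rec in zip(cohort.volumes, cohort.records):
        vol_path = out_dir / f"vol_{rec.subject_id}.nii.gz"
        write_volume(vol, vol_path)
        subjects.append({"subject_id": rec.subject_id, "volume": str(vol_path)})
    clin_path = out_dir / "clinical.csv"
    clinical_frame(cohort.records).to_csv(clin_path, index=False)
    manifest = {
        "seed": cohort.params.seed,
        "params": cohort.params.to_dict(),
        "clinical_csv": str(clin_path),
        "masks": {k: str(v) for k, v in mask_paths.items()},
        "subjects": subjects,
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_cohort(manifest_path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    params = PhantomParams.from_dict(manifest["params"])
    masks = read_mask_set(manifest["masks"])
    clin = pd.read_csv(manifest["clinical_csv"])
    records = [
        ClinicalRecord(**{k: row[k] for k in _CLINICAL_COLUMNS})
        for _, row in clin.iterrows()
    ]
    volumes = [read_volume(s["volume"]) for s in manifest["subjects"]]
    order = {s["subject_id"]: i for i, s in enumerate(manifest["subjects"])}
    records = sorted(records, key=lambda r: order[r.subject_id])
    return Cohort(volumes=volumes, masks=masks, records=records, truth=[],
                  params=params)
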