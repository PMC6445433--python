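"""Synthetic en face angiograms and case-control cohorts with known truth.

Every stage of the quantification pipeline is testable without patient data:

* :func:`generate_angiogram` draws random branching arteriole/venule trees
  plus a jittered-grid capillary mesh, assigns perfused pixels a decorrelation
  value and everything else a Rician noise floor, and returns both the image
  and an :class:`AngiogramTruth` with ground-truth masks and metric values
  computed from the construction.  Macular scans carry an elliptical foveal
  avascular zone bounded by a capillary ring.
* :func:`generate_cohort` draws a 1:1 matched two-group cohort whose
  per-variable group means/SDs follow a :class:`CohortSpec`, with a latent
  severity factor inducing the correlations between the cognitive score and
  the vascular metrics.
* :func:`end_to_end_fixture` writes a miniature study (images + cohort table
  + expected statistical tables) to disk for golden-file pipeline tests.

The vessel geometry model aims for controllable density truth, not
biological realism.  All generation is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw, morphology

from . import vessel_metrics as vm
from .io_roi import (
    EnFaceAngiogram,
    ParticipantRecord,
    cohort_to_frame,
    make_annulus,
    read_angiogram,
    write_angiogram,
)

# ---------------------------------------------------------------------------
# Angiograms
# ---------------------------------------------------------------------------


@dataclass
class VesselParams:
    """Geometry and decorrelation statistics of the synthetic vasculature."""

    n_major_trees: int = 5
    major_calibre_px: tuple[int, int] = (4, 7)  # trunk diameter range
    n_branch_levels: int = 2
    branch_prob: float = 0.02  # per walk step
    step_jitter_rad: float = 0.08
    capillary_spacing_px: int = 14
    capillary_calibre_px: int = 2
    capillary_density: float = 1.0  # scales the number of mesh lines
    vessel_mean: float = 0.40  # capillary decorrelation
    vessel_sd: float = 0.05
    major_vessel_mean: float = 0.60  # large vessels decorrelate brighter
    major_vessel_sd: float = 0.06
    faz_radii_mm: tuple[float, float] = (0.30, 0.25)  # macular scans only


@dataclass
class NoiseParams:
    """Rician background: noise floor ``nu`` + complex Gaussian noise."""

    nu: float = 0.08
    sigma: float = 0.04


@dataclass
class AngiogramTruth:
    """Ground truth for one synthetic angiogram."""

    vessel_mask: np.ndarray
    large_vessel_mask: np.ndarray
    skeleton_len_px: int
    true_vd_percent: dict[str, float]
    true_afi: dict[str, float]
    faz_mask: np.ndarray | None
    faz_area_mm2: float
    seed: int
    vessel_params: VesselParams
    noise_params: NoiseParams


def _draw_tree(
    rng: np.random.Generator,
    size: int,
    centerlines: dict[int, np.ndarray],
    calibre: int,
    max_steps: int,
    params: VesselParams,
) -> None:
    """Random-walk a vessel trunk from a border point inward, branching."""
    edge = rng.integers(0, 4)
    t = rng.uniform(0.1, 0.9) * size
    if edge == 0:
        pos, ang = np.array([0.0, t]), np.pi / 2  # top, heading down
    elif edge == 1:
        pos, ang = np.array([size - 1.0, t]), -np.pi / 2
    elif edge == 2:
        pos, ang = np.array([t, 0.0]), 0.0
    else:
        pos, ang = np.array([t, size - 1.0]), np.pi

    stack = [(pos, ang, calibre, params.n_branch_levels, max_steps)]
    while stack:
        pos, ang, cal, level, steps = stack.pop()
        cl = centerlines.setdefault(cal, np.zeros((size, size), dtype=bool))
        for _ in range(steps):
            # heading: angle 0 = +col, pi/2 = +row
            nxt = pos + 2.0 * np.array([np.sin(ang), np.cos(ang)])
            r0, c0 = int(round(pos[0])), int(round(pos[1]))
            r1, c1 = int(round(nxt[0])), int(round(nxt[1]))
            if not (0 <= r1 < size and 0 <= c1 < size):
                break
            rr, cc = draw.line(r0, c0, r1, c1)
            cl[rr, cc] = True
            pos = nxt
            ang += rng.normal(0.0, params.step_jitter_rad)
            if level > 0 and rng.random() < params.branch_prob:
                b_ang = ang + rng.choice([-1.0, 1.0]) * rng.uniform(0.35, 0.7)
                b_cal = max(cal - 2, 1)
                stack.append((pos.copy(), b_ang, b_cal, level - 1, steps // 2))


def _capillary_mesh(rng: np.random.Generator, size: int, params: VesselParams) -> np.ndarray:
    """Jittered-grid capillary centrelines (both orientations)."""
    mask = np.zeros((size, size), dtype=bool)
    spacing = params.capillary_spacing_px / max(params.capillary_density, 1e-9)
    for axis in (0, 1):
        n_lines = int(np.floor(size / spacing))
        offsets = (np.arange(n_lines) + rng.uniform(0.2, 0.8, n_lines)) * spacing
        for off in offsets:
            jitter = np.cumsum(rng.normal(0.0, 0.35, size))
            jitter -= jitter.mean()
            track = np.clip(np.round(off + jitter).astype(int), 0, size - 1)
            if axis == 0:
                mask[track, np.arange(size)] = True
            else:
                mask[np.arange(size), track] = True
    return mask


def _dilate(mask: np.ndarray, calibre_px: int) -> np.ndarray:
    if calibre_px <= 1:
        return mask.copy()
    radius = calibre_px // 2
    return morphology.dilation(mask, morphology.disk(radius))


def generate_angiogram(
    size_px: int = 304,
    field_mm: float = 3.0,
    scan_type: str = "macula",
    layer: str | None = None,
    vessel_params: VesselParams | None = None,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    quality: tuple[int, int] | None = None,
) -> tuple[EnFaceAngiogram, AngiogramTruth]:
    """Generate one synthetic en face angiogram plus its ground truth.

    Deterministic given ``seed``.  The image is perfused-pixel decorrelation
    (``N(vessel_mean, vessel_sd)``) over a Rician background, clipped to
    [0, 1].  For macular scans an elliptical FAZ is cleared of vessels and
    bounded by a continuous 2-px capillary ring, mirroring the capillary
    arcade that encircles the real avascular zone.
    """
    vp = vessel_params or VesselParams()
    np_ = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)
    mm_per_px = field_mm / size_px

    centerlines: dict[int, np.ndarray] = {}
    for _ in range(vp.n_major_trees):
        cal = int(rng.integers(vp.major_calibre_px[0], vp.major_calibre_px[1] + 1))
        _draw_tree(rng, size_px, centerlines, cal, max_steps=int(0.8 * size_px), params=vp)
    cap_center = _capillary_mesh(rng, size_px, vp)

    large_mask = np.zeros((size_px, size_px), dtype=bool)
    for cal, cl in centerlines.items():
        large_mask |= _dilate(cl, cal)
    cap_mask = _dilate(cap_center, vp.capillary_calibre_px)
    vessel_mask = large_mask | cap_mask

    faz_mask = None
    faz_area_mm2 = 0.0
    if scan_type == "macula":
        a_px = vp.faz_radii_mm[0] / mm_per_px
        b_px = vp.faz_radii_mm[1] / mm_per_px
        cr = cc = size_px // 2
        rr, cc_idx = draw.ellipse(cr, cc, a_px, b_px, shape=(size_px, size_px))
        outer = np.zeros((size_px, size_px), dtype=bool)
        outer[rr, cc_idx] = True
        rr, cc_idx = draw.ellipse(cr, cc, a_px - 2, b_px - 2, shape=(size_px, size_px))
        inner = np.zeros((size_px, size_px), dtype=bool)
        inner[rr, cc_idx] = True
        ring = outer & ~inner
        vessel_mask = (vessel_mask & ~outer) | ring
        large_mask &= ~outer
        faz_mask = inner
        faz_area_mm2 = float(inner.sum()) * (mm_per_px * 1000.0) ** 2 / 1e6

    if not vessel_mask.any():
        raise ValueError("vessel parameters yield zero vessel pixels")

    background = np.hypot(
        np_.nu + np_.sigma * rng.standard_normal((size_px, size_px)),
        np_.sigma * rng.standard_normal((size_px, size_px)),
    )
    cap_vals = rng.normal(vp.vessel_mean, vp.vessel_sd, (size_px, size_px))
    major_vals = rng.normal(vp.major_vessel_mean, vp.major_vessel_sd, (size_px, size_px))
    vessel_vals = np.where(large_mask, major_vals, cap_vals)
    pixels = np.clip(np.where(vessel_mask, vessel_vals, background), 0.0, 1.0)

    image = EnFaceAngiogram(
        pixels=pixels,
        field_width_mm=field_mm,
        scan_type=scan_type,
        layer=layer,
        quality=quality,
    )

    roi_name, roi_mm = (
        ("parafovea", vm.PARAFOVEA_MM)
        if scan_type == "macula"
        else ("peripapillary", vm.PERIPAPILLARY_MM)
    )
    roi = make_annulus(image, *roi_mm)
    n_roi = roi.pixel_mask.sum()
    true_vd = {
        "global": 100.0 * vessel_mask.mean(),
        roi_name: 100.0 * float((vessel_mask & roi.pixel_mask).sum()) / n_roi,
    }
    true_afi = {
        "global": float(pixels[vessel_mask].mean()),
        roi_name: float(pixels[vessel_mask & roi.pixel_mask].mean()),
    }
    truth = AngiogramTruth(
        vessel_mask=vessel_mask,
        large_vessel_mask=large_mask,
        skeleton_len_px=int(morphology.skeletonize(vessel_mask).sum()),
        true_vd_percent=true_vd,
        true_afi=true_afi,
        faz_mask=faz_mask,
        faz_area_mm2=faz_area_mm2,
        seed=seed,
        vessel_params=vp,
        noise_params=np_,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class VariableSpec:
    """Per-variable group moments and latent-severity loading.

    ``loading`` in [0, 1] is the correlation of the variable with the latent
    severity factor within each group; the implied within-group correlation
    between two variables is the product of their loadings.
    """

    impaired_mean: float
    impaired_sd: float
    control_mean: float
    control_sd: float
    loading: float = 0.0
    clip: tuple[float | None, float | None] = (None, None)
    integer: bool = False


@dataclass
class CohortSpec:
    """Moment structure of a synthetic 1:1 matched two-group cohort."""

    n_per_group: int = 16
    variables: dict[str, VariableSpec] = field(default_factory=dict)
    n_ead: int = 3  # impaired arm split: n_ead early-AD, the rest aMCI
    male_fraction: float = 3.0 / 16.0
    race_probs: dict[str, float] = field(
        default_factory=lambda: {"Caucasian": 0.90, "AfricanAmerican": 0.06, "Hispanic": 0.04}
    )
    age_mean: float = 73.6
    age_sd: float = 7.7
    match_age_years: float = 3.0
    cdr_impaired_mix: tuple[float, float, float] = (0.5, 1.0, 0.12)  # values + P(1.0)
    inter_eye_sd_frac: float = 0.15  # OS metric jitter, fraction of group SD
    seed: int = 0


#: fields of ParticipantRecord (everything else goes into the metrics dict)
_RECORD_FIELDS = {
    "moca",
    "craft_imm",
    "craft_del",
    "ravlt_del",
    "education_years",
    "iop_mmhg",
    "interval_years",
}


def default_cohort_spec(n_per_group: int = 16, seed: int = 0) -> CohortSpec:
    """Defaults reproducing the moment structure of a 16+16 early-cognitive-
    impairment (aMCI/eAD) vs matched-control OCTA study."""
    v = {
        # cognition (instrument ranges enforced by clipping)
        "moca": VariableSpec(20.25, 3.80, 27.06, 2.21, loading=0.80, clip=(0, 30), integer=True),
        "craft_imm": VariableSpec(9.56, 2.70, 17.00, 2.68, loading=0.70, clip=(0, 25), integer=True),
        "craft_del": VariableSpec(5.38, 4.53, 16.19, 2.88, loading=0.70, clip=(0, 25), integer=True),
        "ravlt_del": VariableSpec(2.06, 2.79, 10.81, 3.17, loading=0.70, clip=(0, 15), integer=True),
        # demographics / clinical
        "education_years": VariableSpec(16.50, 2.13, 16.56, 1.75),
        "iop_mmhg": VariableSpec(16.19, 2.46, 16.38, 2.22),
        "interval_years": VariableSpec(0.49, 0.45, 0.40, 0.44, clip=(0, None)),
        # vascular metrics (parafoveal and peripapillary)
        "scp_vd": VariableSpec(40.67, 5.23, 44.50, 4.11, loading=0.50),
        "scp_vld": VariableSpec(16.41, 3.60, 16.73, 2.64, loading=0.10),
        "scp_afi": VariableSpec(0.376, 0.041, 0.407, 0.037, loading=0.40),
        "rpc_vd_global": VariableSpec(46.93, 5.04, 49.63, 1.85, loading=0.40),
        "rpc_vd_superior": VariableSpec(47.42, 7.31, 49.18, 3.91, loading=0.30),
        "rpc_vd_capillary": VariableSpec(34.96, 4.78, 37.85, 1.58, loading=0.40),
        "rpc_vld": VariableSpec(15.23, 1.87, 16.07, 1.21, loading=0.55),
        "svc_vd": VariableSpec(43.16, 4.88, 45.00, 3.58, loading=0.30),
        "svc_vld": VariableSpec(16.72, 2.01, 17.30, 1.41, loading=0.30),
        # supplementary structural metrics
        "wr_vd": VariableSpec(44.3, 4.6, 47.4, 3.4, loading=0.40),
        "dcp_vd": VariableSpec(52.2, 4.1, 53.0, 3.9, loading=0.15),
        "faz_area_mm2": VariableSpec(0.29, 0.10, 0.28, 0.09, clip=(0, None)),
        "rnfl_um": VariableSpec(105.0, 10.0, 106.5, 9.0, loading=0.10),
    }
    return CohortSpec(n_per_group=n_per_group, variables=v, seed=seed)


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    quality_dropout: float = 0.0,
) -> list[ParticipantRecord]:
    """Draw a per-eye cohort table (OD and OS rows per participant).

    Per participant a latent severity ``u ~ N(0, 1)`` is shared by every
    loaded variable: ``x = mu_g + sd_g (lambda u + sqrt(1 - lambda^2) eps)``,
    so group means/SDs match the spec up to sampling error and loadings set
    the within-group correlation structure.  Controls are matched 1:1 to
    cases on age (within ``match_age_years``), gender and race.
    ``quality_dropout`` is the probability that an eye fails the device
    quality gates (its SSI is set below threshold).
    """
    if spec is None:
        spec = default_cohort_spec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    for name, v in spec.variables.items():
        if not -1.0 <= v.loading <= 1.0:
            raise ValueError(
                f"variable {name!r}: loading {v.loading} implies negative residual "
                "variance (must lie in [-1, 1])"
            )
        if v.impaired_sd <= 0 or v.control_sd <= 0:
            raise ValueError(f"variable {name!r}: SDs must be positive")
    if spec.n_per_group < 2:
        raise ValueError("need n_per_group >= 2")

    races = list(spec.race_probs)
    race_p = np.array([spec.race_probs[r] for r in races], float)
    race_p = race_p / race_p.sum()
    n_ead = min(spec.n_ead, spec.n_per_group)
    clip_events = 0
    records: list[ParticipantRecord] = []

    for i in range(spec.n_per_group):
        gender = "M" if rng.random() < spec.male_fraction else "F"
        race = races[rng.choice(len(races), p=race_p)]
        age_control = float(rng.normal(spec.age_mean, spec.age_sd))
        age_impaired = age_control + float(
            rng.uniform(-spec.match_age_years, spec.match_age_years)
        )
        group_i = "eAD" if i < n_ead else "aMCI"
        for arm, group, age in (
            ("I", group_i, age_impaired),
            ("C", "control", age_control),
        ):
            u = rng.standard_normal()
            fields: dict[str, float] = {}
            metrics: dict[str, float] = {}
            for name, v in spec.variables.items():
                mu, sd = (
                    (v.impaired_mean, v.impaired_sd)
                    if arm == "I"
                    else (v.control_mean, v.control_sd)
                )
                eps = rng.standard_normal()
                val = mu + sd * (v.loading * u + np.sqrt(1 - v.loading**2) * eps)
                lo, hi = v.clip
                clipped = (lo is not None and val < lo) or (hi is not None and val > hi)
                clip_events += clipped
                if lo is not None or hi is not None:
                    val = float(np.clip(val, lo if lo is not None else -np.inf,
                                        hi if hi is not None else np.inf))
                if v.integer:
                    val = float(round(val))
                (fields if name in _RECORD_FIELDS else metrics)[name] = val
            # CDR on its discrete scale
            if arm == "I":
                lo_v, hi_v, p_hi = spec.cdr_impaired_mix
                cdr = hi_v if rng.random() < p_hi else lo_v
            else:
                cdr = 0.0
            pid = f"{arm}{i + 1:02d}"
            for eye in ("OD", "OS"):
                eye_metrics = dict(metrics)
                if eye == "OS":
                    for name in list(eye_metrics):
                        v = spec.variables[name]
                        sd = v.impaired_sd if arm == "I" else v.control_sd
                        eye_metrics[name] += float(
                            rng.normal(0.0, spec.inter_eye_sd_frac * sd)
                        )
                        lo, hi = v.clip
                        if lo is not None or hi is not None:
                            eye_metrics[name] = float(
                                np.clip(eye_metrics[name],
                                        lo if lo is not None else -np.inf,
                                        hi if hi is not None else np.inf)
                            )
                fails = rng.random() < quality_dropout
                records.append(
                    ParticipantRecord(
                        id=pid,
                        group=group,
                        age=round(age, 1),
                        gender=gender,
                        race=race,
                        eye=eye,
                        sq_macula=float(rng.integers(7, 10)) if not fails else 5.0,
                        ssi_macula=float(np.round(rng.normal(62, 5), 1))
                        if not fails
                        else 42.0,
                        sq_disc=float(rng.integers(7, 10)) if not fails else 5.0,
                        ssi_disc=float(np.round(rng.normal(58, 5), 1))
                        if not fails
                        else 38.0,
                        cdr=cdr,
                        metrics=eye_metrics,
                        **fields,
                    )
                )
    if clip_events:
        import logging

        logging.getLogger(__name__).info(
            "generate_cohort: %d values clipped to instrument ranges", clip_events
        )
    return records


# ---------------------------------------------------------------------------
# End-to-end fixture
# ---------------------------------------------------------------------------


def _participant_images(
    pid_seed: int, size_px: int, capillary_density: float
) -> list[EnFaceAngiogram]:
    """One macular SCP and one disc RPC scan for a synthetic participant."""
    vp_mac = VesselParams(capillary_density=capillary_density)
    vp_disc = replace(vp_mac, faz_radii_mm=(0.0, 0.0))
    scp, _ = generate_angiogram(
        size_px=size_px, field_mm=3.0, scan_type="macula", layer="SCP",
        vessel_params=vp_mac, seed=pid_seed, quality=(8, 60),
    )
    rpc, _ = generate_angiogram(
        size_px=size_px, field_mm=4.5, scan_type="disc", layer="RPC",
        vessel_params=vp_disc, seed=pid_seed + 1, quality=(8, 55),
    )
    return [scp, rpc]


def end_to_end_fixture(
    seed: int,
    out_dir: str | Path,
    n_per_group: int = 4,
    size_px: int = 152,
    impaired_density_factor: float = 1.0,
) -> dict:
    """Write a miniature study to ``out_dir`` and its expected analysis output.

    Layout: ``images/<pid>_SCP.png`` and ``<pid>_RPC.png`` per participant,
    ``cohort.csv`` (demographics, cognition and quality; no metric columns —
    those are produced by quantification), and ``expected/table*.csv`` — the
    tables the pipeline must reproduce bit-for-bit when run on the images and
    cohort table.  ``impaired_density_factor`` scales the capillary mesh
    density of impaired participants' scans (1.0 = no group difference in the
    images).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "expected").mkdir(parents=True, exist_ok=True)

    spec = default_cohort_spec(n_per_group=n_per_group, seed=seed)
    records = generate_cohort(spec)
    od_records = [r for r in records if r.eye == "OD"]

    analysis: list[ParticipantRecord] = []
    for idx, rec in enumerate(od_records):
        density = impaired_density_factor if rec.impaired else 1.0
        images = _participant_images(seed * 1000 + idx * 7, size_px, density)
        disk_images = []
        for img in images:
            path = out / "images" / f"{rec.id}_{img.layer}.png"
            write_angiogram(img, path)
            # quantify what is actually on disk (16-bit quantisation included)
            disk_images.append(
                read_angiogram(path, img.field_width_mm, img.scan_type,
                               layer=img.layer, quality=img.quality)
            )
        results = vm.quantify_eye(disk_images, vm.QuantifyConfig(eye=rec.eye))
        rec = replace(rec, metrics=metrics_to_columns(results))
        analysis.append(rec)

    table = cohort_to_frame(analysis)
    table = table.drop(columns=[c for c in table.columns if c in
                                {m for r in analysis for m in r.metrics}])
    table.to_csv(out / "cohort.csv", index=False,
                 float_format=lambda v: repr(float(v)))

    from .cohort_statistics import reproduce_tables

    tables = reproduce_tables(analysis)
    for name in ("table1", "table2", "table3", "tableS1"):
        tables[name].to_csv(out / "expected" / f"{name}.csv", index=False)
    return {"records": analysis, "tables": tables, "dir": out}


#: (layer, roi, metric) -> canonical cohort-table column
_RESULT_COLUMNS = {
    ("SCP", "parafovea", "vd"): "scp_vd",
    ("SCP", "parafovea", "vld"): "scp_vld",
    ("SCP", "parafovea", "afi"): "scp_afi",
    ("SCP", "fovea", "faz_area_mm2"): "faz_area_mm2",
    ("whole_retina", "parafovea", "vd"): "wr_vd",
    ("whole_retina", "fovea", "faz_area_mm2"): "faz_area_mm2",
    ("DCP", "parafovea", "vd"): "dcp_vd",
    ("RPC", "peripapillary", "vd"): "rpc_vd_global",
    ("RPC", "peripapillary_superior", "vd"): "rpc_vd_superior",
    ("RPC", "peripapillary", "microcap_vd"): "rpc_vd_capillary",
    ("RPC", "peripapillary", "vld"): "rpc_vld",
    ("SVC", "peripapillary", "vd"): "svc_vd",
    ("SVC", "peripapillary", "vld"): "svc_vld",
}


def metrics_to_columns(results: Sequence[vm.MetricResult]) -> dict[str, float]:
    """Map per-eye MetricResults onto canonical cohort-table columns."""
    out: dict[str, float] = {}
    for res in results:
        col = _RESULT_COLUMNS.get((res.layer, res.roi, res.metric))
        if col is not None:
            out[col] = res.value
    return out


def directory_hash(path: str | Path) -> str:
    """SHA-256 over the sorted relative paths and contents of a directory."""
    h = hashlib.sha256()
    root = Path(path)
    for f in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(str(f.relative_to(root)).encode())
        h.update(f.read_bytes())
    return h.hexdigest()
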