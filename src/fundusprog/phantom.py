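"""Synthetic longitudinal fundus-phantom cohorts.

Real longitudinal AMD imaging cohorts (AREDS, UK Biobank) are
controlled-access, so this module generates stand-in cohorts with the
statistical and anatomical structure the rest of the package assumes:

* each eye has a fixed gross anatomy (optic disc, vessel arcades) that is
  identical across all of its visits;
* AMD severity follows a monotone non-decreasing random walk on the
  12-step ordinal scale (advanced AMD, severity >= 10, is irreversible);
* severity drives macular lesions: drusen load grows with severity, and
  severities >= 10 add a late-AMD feature (pale atrophic patch or dark
  neovascular blot);
* visit schedules live on a 6-month grid (indices 0-26) with independent
  visit drop-out, and the resulting (current, future) pair labels are
  strongly imbalanced, like the published cohort statistics.

Rendering is deliberately schematic: anti-aliased discs and polylines,
not photorealism.  Everything is a pure function of the seeds carried in
the config/phantom objects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image

ADVANCED_THRESHOLD = 10
MAX_SEVERITY = 12
MAX_VISIT_INDEX = 26

#: radial extent (as a fraction of the retina radius) of the macular
#: annulus in which drusen and late-AMD features are placed.
MACULA_INNER_FRAC = 0.02
MACULA_OUTER_FRAC = 0.62

# Default baseline-severity distribution over the 13 ordinal levels and the
# per-6-month step-up probability.  Calibrated once by simulation so that
# gap-4 pair labels land near the published 83.9% / 3.3% / 12.8% split.
_DEFAULT_ONSET = tuple(
    w / 965.0
    for w in (270, 120, 90, 70, 65, 60, 55, 50, 50, 50, 45, 25, 15)
)


@dataclass(frozen=True)
class ProgressionConfig:
    """Parameters of the monotone severity random walk."""

    step_up_prob: float = 0.08
    max_step: int = 2
    onset_severity_dist: tuple = _DEFAULT_ONSET

    def __post_init__(self):
        if not 0.0 <= self.step_up_prob <= 1.0:
            raise ValueError(f"step_up_prob must be in [0,1], got {self.step_up_prob}")
        if self.max_step < 1:
            raise ValueError("max_step must be >= 1")
        p = np.asarray(self.onset_severity_dist, dtype=float)
        if p.shape != (MAX_SEVERITY + 1,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("onset_severity_dist must be a length-13 probability vector")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings."""

    n_subjects: int = 100
    visit_grid: tuple = tuple(range(0, MAX_VISIT_INDEX + 1, 2))
    missing_visit_prob: float = 0.15
    image_size: int = 224
    master_seed: int = 0
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)

    def __post_init__(self):
        grid = tuple(self.visit_grid)
        if len(grid) == 0:
            raise ValueError("visit_grid must be non-empty")
        if list(grid) != sorted(set(grid)):
            raise ValueError("visit_grid must be sorted and duplicate-free")
        if grid[0] < 0 or grid[-1] > MAX_VISIT_INDEX:
            raise ValueError(f"visit_grid must lie within 0..{MAX_VISIT_INDEX}")
        if not 0.0 <= self.missing_visit_prob <= 1.0:
            raise ValueError("missing_visit_prob must be in [0,1]")
        object.__setattr__(self, "visit_grid", grid)


@dataclass(frozen=True)
class EyePhantom:
    """Fixed per-eye anatomy; geometry is a pure function of geometry_seed."""

    eye_id: str
    geometry_seed: int
    optic_disc_center: tuple   # (row, col) as fractions of the image side
    vessel_tree: tuple         # tuple of (3, 2) control-point arrays (fractions)
    base_pigmentation: float
    lesion_seed: int
    late_form: str             # "atrophy" (pale patch) or "neovascular" (dark blot)
    drusen_centers: tuple      # (N, 2) fractions relative to image side
    drusen_radii: tuple        # base radii as fractions of the image side


_N_DRUSEN_CANDIDATES = 2 * MAX_SEVERITY  # revealed progressively with severity


def make_phantom(eye_id: str, geometry_seed: int, side: str = "L",
                 lesion_seed: int | None = None) -> EyePhantom:
    """Build the fixed anatomy of one eye.

    ``side`` places the optic disc nasally (left column for "L", right for
    "R").  ``lesion_seed`` decouples lesion placement from gross geometry;
    it defaults to a value derived from ``geometry_seed``.
    """
    rng = np.random.default_rng(geometry_seed)
    if lesion_seed is None:
        lesion_seed = int(geometry_seed) * 2654435761 % (2**31 - 1)

    disc_col = 0.18 if side == "L" else 0.82
    disc = (0.5 + rng.uniform(-0.06, 0.06), disc_col + rng.uniform(-0.03, 0.03))

    # Vessel arcades: quadratic Bezier curves fanning out from the disc.
    n_vessels = 6
    sign = 1.0 if side == "L" else -1.0
    vessels = []
    for i in range(n_vessels):
        ang = rng.uniform(-1.25, 1.25) + (i - (n_vessels - 1) / 2) * 0.55
        reach = rng.uniform(0.45, 0.80)
        end = (disc[0] + reach * np.sin(ang),
               disc[1] + sign * reach * np.cos(ang) * 0.9)
        mid = ((disc[0] + end[0]) / 2 + rng.uniform(-0.10, 0.10),
               (disc[1] + end[1]) / 2 + sign * rng.uniform(0.02, 0.14))
        vessels.append(np.array([disc, mid, end], dtype=float))

    lrng = np.random.default_rng(lesion_seed)
    late_form = "atrophy" if lrng.random() < 0.7 else "neovascular"
    theta = lrng.uniform(0.0, 2 * np.pi, size=_N_DRUSEN_CANDIDATES)
    rho = 0.48 * (MACULA_INNER_FRAC +
                  (MACULA_OUTER_FRAC - MACULA_INNER_FRAC) * np.sqrt(lrng.random(_N_DRUSEN_CANDIDATES)))
    centers = np.stack([0.5 + rho * np.sin(theta), 0.5 + rho * np.cos(theta)], axis=1)
    radii = lrng.uniform(0.012, 0.030, size=_N_DRUSEN_CANDIDATES)

    return EyePhantom(
        eye_id=eye_id,
        geometry_seed=int(geometry_seed),
        optic_disc_center=disc,
        vessel_tree=tuple(np.asarray(v) for v in vessels),
        base_pigmentation=float(rng.uniform(0.0, 1.0)),
        lesion_seed=int(lesion_seed),
        late_form=late_form,
        drusen_centers=tuple(map(tuple, centers)),
        drusen_radii=tuple(radii),
    )


def advance_severity(s: int, cfg: ProgressionConfig, rng: np.random.Generator) -> int:
    """One 6-month severity step: increment with prob ``step_up_prob``, capped at 12."""
    if not 0 <= s <= MAX_SEVERITY:
        raise ValueError(f"severity must be in 0..{MAX_SEVERITY}, got {s}")
    if rng.random() < cfg.step_up_prob:
        step = int(rng.integers(1, cfg.max_step + 1))
        return min(MAX_SEVERITY, s + step)
    return int(s)


def severity_trajectory(cfg: ProgressionConfig, rng: np.random.Generator,
                        n_steps: int = MAX_VISIT_INDEX) -> np.ndarray:
    """Severity at every 6-month index 0..n_steps (monotone, capped at 12)."""
    s = int(rng.choice(MAX_SEVERITY + 1, p=np.asarray(cfg.onset_severity_dist)))
    traj = [s]
    for _ in range(n_steps):
        s = advance_severity(s, cfg, rng)
        traj.append(s)
    return np.asarray(traj, dtype=int)


# --------------------------------------------------------------------------
# rendering

def _disc_mask(shape, center_rc, radius, aspect=1.0):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center_rc[0]) ** 2 + ((xx - center_rc[1]) / aspect) ** 2) <= radius**2


def _stamp_polyline(mask, pts, width):
    """Rasterize a polyline (array of (row, col) points) with ~width thickness."""
    h, w = mask.shape
    r = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    c = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    rad = max(0, int(round(width)) - 1)
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            if dr * dr + dc * dc <= rad * rad + rad:
                mask[np.clip(r + dr, 0, h - 1), np.clip(c + dc, 0, w - 1)] = True


def render_fundus_layers(phantom: EyePhantom, severity: int, size: int):
    """Render one visit and return ``(image_uint8, masks)``.

    ``masks`` holds boolean layers: retina, disc, vessels, drusen, late.
    The drusen and late masks exclude vessel/disc pixels so that vessel and
    disc pixels are bit-identical across severities of the same phantom.
    """
    if size < 32:
        raise ValueError(f"image size must be >= 32, got {size}")
    if not 0 <= severity <= MAX_SEVERITY:
        raise ValueError(f"severity must be in 0..{MAX_SEVERITY}, got {severity}")

    S = size
    img = np.full((S, S, 3), 0.04, dtype=np.float64)
    yy, xx = np.ogrid[:S, :S]
    cy = cx = (S - 1) / 2.0
    R = 0.48 * S

    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    retina = r2 <= R * R
    shade = 1.0 - 0.25 * np.clip(r2 / (R * R), 0, 1)
    base = np.array([0.70, 0.33, 0.10]) * (0.75 + 0.40 * phantom.base_pigmentation)
    img[retina] = base[None, :] * shade[retina, None]

    # fovea: mild central darkening
    fov = np.exp(-r2 / (2 * (0.10 * S) ** 2))
    img[retina] *= (1.0 - 0.30 * fov[retina])[:, None]

    # late-AMD feature (severity >= 10): atrophic patch or neovascular blot
    late = np.zeros((S, S), dtype=bool)
    if severity >= ADVANCED_THRESHOLD:
        lrng = np.random.default_rng(phantom.lesion_seed + 1)
        off = lrng.uniform(-0.05, 0.05, size=2) * S
        rad = (0.18 + 0.06 * (severity - ADVANCED_THRESHOLD + 1)) * R
        late = _disc_mask((S, S), (cy + off[0], cx + off[1]), rad) & retina
        color = np.array([0.88, 0.86, 0.70]) if phantom.late_form == "atrophy" \
            else np.array([0.22, 0.07, 0.05])
        img[late] = 0.15 * img[late] + 0.85 * color

    # drusen: progressively revealed, progressively enlarged candidate blobs
    drusen = np.zeros((S, S), dtype=bool)
    if severity > 0:
        k = min(_N_DRUSEN_CANDIDATES, 2 * severity)
        scale = 1.0 + 0.10 * severity
        for (fr, fc), rad in zip(phantom.drusen_centers[:k], phantom.drusen_radii[:k]):
            m = _disc_mask((S, S), (fr * S, fc * S), max(1.0, rad * scale * S))
            drusen |= m & retina
        img[drusen] = 0.25 * img[drusen] + 0.75 * np.array([0.95, 0.85, 0.45])

    # vessels then optic disc on top: identical across severities
    vmask = np.zeros((S, S), dtype=bool)
    t = np.linspace(0.0, 1.0, 3 * S)[:, None]
    for ctrl in phantom.vessel_tree:
        p = ((1 - t) ** 2 * ctrl[0] + 2 * t * (1 - t) * ctrl[1] + t**2 * ctrl[2]) * S
        _stamp_polyline(vmask, p, width=max(1.0, S / 56.0))
    vmask &= retina
    img[vmask] = np.array([0.42, 0.09, 0.07])

    dc = (phantom.optic_disc_center[0] * S, phantom.optic_disc_center[1] * S)
    disc = _disc_mask((S, S), dc, 0.10 * R, aspect=1.25) & retina
    img[disc] = np.array([0.95, 0.87, 0.55])

    masks = {
        "retina": retina,
        "disc": disc,
        "vessels": vmask & ~disc,
        "drusen": drusen & ~vmask & ~disc,
        "late": late & ~vmask & ~disc,
    }
    return (np.clip(img, 0, 1) * 255).astype(np.uint8), masks


def render_fundus(phantom: EyePhantom, severity: int, size: int) -> np.ndarray:
    """RGB uint8 phantom fundus image; deterministic in (phantom, severity, size)."""
    img, _ = render_fundus_layers(phantom, severity, size)
    return img


def macula_annulus_mask(size: int) -> np.ndarray:
    """Boolean mask of the macular annulus in which lesions are placed."""
    S = size
    yy, xx = np.ogrid[:S, :S]
    cy = cx = (S - 1) / 2.0
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / (0.48 * S)
    return (r >= MACULA_INNER_FRAC) & (r <= MACULA_OUTER_FRAC + 0.08)


# --------------------------------------------------------------------------
# cohort simulation

def _eye_streams(master_seed: int, subj_idx: int, eye_idx: int):
    ss = np.random.SeedSequence([master_seed, subj_idx, eye_idx])
    traj_ss, miss_ss, geom_ss, les_ss, age_ss = ss.spawn(5)
    return (np.random.default_rng(traj_ss), np.random.default_rng(miss_ss),
            int(geom_ss.generate_state(1)[0] % (2**31 - 1)),
            int(les_ss.generate_state(1)[0] % (2**31 - 1)),
            np.random.default_rng(age_ss))


def simulate_cohort(cfg: SimConfig, out_dir: str | None = None):
    """Simulate a longitudinal two-eye cohort.

    Returns ``(manifest, phantoms)`` where ``manifest`` is a pandas
    DataFrame with the cohort-manifest schema (subject_id, eye,
    visit_index, image_path, severity, age) and ``phantoms`` maps
    ``(subject_id, eye)`` to the eye's :class:`EyePhantom`.  When
    ``out_dir`` is given, PNG images are rendered and written there and
    ``image_path`` points at them; otherwise ``image_path`` holds the
    relative file name only and no files are written (images can then be
    rendered on demand from the phantom).
    """
    import pandas as pd

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)

    rows = []
    phantoms = {}
    for si in range(cfg.n_subjects):
        subject = f"S{si:05d}"
        for ei, eye in enumerate(("L", "R")):
            rng_t, rng_m, geom_seed, les_seed, rng_a = _eye_streams(cfg.master_seed, si, ei)
            traj = severity_trajectory(cfg.progression, rng_t)
            phantom = make_phantom(f"{subject}_{eye}", geom_seed, side=eye,
                                   lesion_seed=les_seed)
            phantoms[(subject, eye)] = phantom
            age0 = float(rng_a.uniform(55.0, 80.0))
            for v in cfg.visit_grid:
                if rng_m.random() < cfg.missing_visit_prob:
                    continue
                fname = f"{subject}_{eye}_v{v:02d}.png"
                path = fname
                if out_dir is not None:
                    path = os.path.join(out_dir, fname)
                    img = render_fundus(phantom, int(traj[v]), cfg.image_size)
                    Image.fromarray(img).save(path)
                rows.append({
                    "subject_id": subject, "eye": eye, "visit_index": int(v),
                    "image_path": path, "severity": int(traj[v]),
                    "age": round(age0 + 0.5 * v, 1),
                })
    manifest = pd.DataFrame(rows, columns=["subject_id", "eye", "visit_index",
                                           "image_path", "severity", "age"])
    return manifest, phantoms
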