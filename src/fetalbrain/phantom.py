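"""Synthetic 7-tissue fetal-brain phantoms with known gestational age.

Each phantom is a nest of ellipsoidal compartments: an outer CSF shell (ECF),
a cortical gray-matter shell (FGM), a white-matter interior (WM), and four
small structures strictly inside the WM — paired ventricles (VC), a posterior
cerebellar blob (CBM), a central deep-gray blob (DGM) and an inferior
brainstem cylinder (BSTM).  Every semi-axis scales affinely with gestational
age, ``r(ga) = r20 * (1 + 0.035 * (ga - 20))``, so the brain's maximum 3D
diameter grows strictly with GA over the 20-33 week range and geometric
features carry a recoverable age signal.

Intensities mimic T2-weighted contrast only loosely: each tissue gets a
distinct mean on [0.2, 1.0] plus additive Gaussian noise.  There is no MRI
physics (no partial volume, no bias field by default, no motion), so results
on phantoms demonstrate pipeline correctness, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, LabelVolume

GA_MIN, GA_MAX = 20.0, 33.0

#: affine growth rate of all semi-axes per gestational week past week 20
GROWTH_PER_WEEK = 0.035

#: per-tissue mean intensities (fraction of dynamic range), labels 1..7.
#: Levels are spaced so the smallest gap between any two tissues (0.10) is
#: five noise standard deviations at the default noise_sd, i.e. tissues are
#: genuinely separable by intensity as on T2 (CSF bright, WM dark).
TISSUE_MEANS = {
    1: 0.95,  # ECF: CSF bright on T2
    2: 0.45,  # FGM
    3: 0.22,  # WM, darkest tissue
    4: 0.80,  # VC: ventricular CSF
    5: 0.55,  # CBM
    6: 0.68,  # DGM
    7: 0.34,  # BSTM
}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ga_weeks: float = 26.0
    noise_sd: float = 0.02
    seed: int = 0
    bias_field: bool = False

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 32 for s in self.shape):
            raise ValueError(f"shape components must be >= 32, got {self.shape}")
        if not (GA_MIN <= self.ga_weeks <= GA_MAX):
            raise ValueError(f"ga_weeks must lie in [{GA_MIN}, {GA_MAX}], got {self.ga_weeks}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def growth_factor(ga_weeks: float) -> float:
    return 1.0 + GROWTH_PER_WEEK * (ga_weeks - 20.0)


def _ellipsoid(coords, center, semi):
    """Normalized squared ellipsoid coordinate; <= 1 is inside."""
    x, y, z = coords
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2


def make_phantom(cfg: PhantomConfig) -> tuple[ImageVolume, LabelVolume, float]:
    """Generate one phantom; identical configs give byte-identical output."""
    nx, ny, nz = cfg.shape
    g = growth_factor(cfg.ga_weeks)
    # outer brain semi-axes (voxels), slightly anisotropic
    a1 = np.array([0.30 * nx, 0.27 * ny, 0.25 * nz]) * g
    center = np.array([(nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0])
    if np.any(a1 >= np.array(cfg.shape) / 2.0 - 1.0):
        raise ValueError(
            f"shape {cfg.shape} too small for the brain at GA {cfg.ga_weeks} weeks"
        )

    coords = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )

    labels = np.zeros(cfg.shape, dtype=np.uint8)

    outer = _ellipsoid(coords, center, a1) <= 1.0
    fgm_outer = _ellipsoid(coords, center, 0.88 * a1) <= 1.0
    wm_outer = _ellipsoid(coords, center, 0.76 * a1) <= 1.0
    labels[outer] = 1                        # ECF shell
    labels[fgm_outer] = 2                    # cortical shell
    labels[wm_outer] = 3                     # WM interior

    def paint(label, offset_frac, semi_frac):
        c = center + np.asarray(offset_frac) * a1
        s = np.asarray(semi_frac) * a1
        inside = _ellipsoid(coords, c, s) <= 1.0
        labels[inside & wm_outer] = label

    # interior structures, strictly inside the WM compartment; sizes chosen so
    # tissue volume fractions approach those of real fetal anatomy
    paint(5, (0.0, -0.40, -0.20), (0.28, 0.26, 0.24))   # CBM, posterior-inferior
    paint(6, (0.0, 0.12, 0.10), (0.26, 0.23, 0.21))     # DGM, central
    paint(4, (+0.38, 0.14, 0.24), (0.21, 0.18, 0.18))   # VC right
    paint(4, (-0.38, 0.14, 0.24), (0.21, 0.18, 0.18))   # VC left
    # BSTM: inferior cylinder along z
    x, y, z = coords
    cz0 = center[2] - 0.54 * a1[2]
    cz1 = center[2] - 0.14 * a1[2]
    r_b = 0.16 * a1[:2]
    cyl = (
        (((x - center[0]) / r_b[0]) ** 2 + ((y - (center[1] - 0.10 * a1[1])) / r_b[1]) ** 2 <= 1.0)
        & (z >= cz0)
        & (z <= cz1)
    )
    labels[cyl & wm_outer] = 7

    rng = np.random.default_rng(cfg.seed)
    intensity = np.zeros(cfg.shape, dtype=np.float64)
    for lab, mean in TISSUE_MEANS.items():
        intensity[labels == lab] = mean
    if cfg.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    if cfg.bias_field:
        # low-frequency multiplicative field, +-10%
        fx = np.linspace(-1, 1, nx)[:, None, None]
        fy = np.linspace(-1, 1, ny)[None, :, None]
        phase = rng.uniform(0, 2 * np.pi)
        intensity = intensity * (1.0 + 0.1 * np.sin(1.5 * fx + phase) * np.cos(1.5 * fy))

    img = ImageVolume(intensity.astype(np.float32), spacing=cfg.spacing)
    lab = LabelVolume(labels, spacing=cfg.spacing)
    return img, lab, float(cfg.ga_weeks)


def make_cohort(
    n: int,
    ga_low: float = GA_MIN,
    ga_high: float = GA_MAX,
    seed: int = 0,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    noise_sd: float = 0.03,
) -> list[tuple[ImageVolume, LabelVolume, float]]:
    """Generate ``n`` phantoms with GA drawn uniformly in [ga_low, ga_high].

    Per-subject seeds derive deterministically from the cohort seed, so a
    cohort is reproducible and individual subjects are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (GA_MIN <= ga_low <= ga_high <= GA_MAX):
        raise ValueError(f"GA range [{ga_low}, {ga_high}] outside [{GA_MIN}, {GA_MAX}]")
    rng = np.random.default_rng(seed)
    gas = rng.uniform(ga_low, ga_high, size=n)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n)
    cohort = []
    for ga, s in zip(gas, subject_seeds):
        cfg = PhantomConfig(
            shape=shape, spacing=spacing, ga_weeks=float(ga), noise_sd=noise_sd, seed=int(s)
        )
        cohort.append(make_phantom(cfg))
    return cohort


def train_test_split_cohort(cohort, n_train: int = 64, n_test: int = 16):
    """Deterministic leading/trailing split mirroring an 80/20 protocol."""
    if n_train + n_test > len(cohort):
        raise ValueError(
            f"cohort of {len(cohort)} cannot be split into {n_train}+{n_test}"
        )
    return cohort[:n_train], cohort[n_train : n_train + n_test]
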