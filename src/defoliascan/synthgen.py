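"""Synthetic paired canopy spectra and defoliated-crown point clouds.

The generator reproduces the statistical structure the downstream
analysis assumes, at the study's stated conditions: 284 trees in three
damage stages (103 mild / 99 moderate / 82 severe), 145-band reflectance
spectra on a 400-1000 nm grid, and per-tree ground-normalized LiDAR
returns with intensity. Defoliation percentage (DP) drives every signal:

* spectra — reflectance rises in the red-edge window (680-760 nm) and
  falls on the NIR plateau (900-1000 nm) as DP grows, on top of a fixed
  healthy-conifer template plus smooth (correlated across bands) and
  white noise;
* crowns — a paraboloid crown is fully sampled, then a DP-proportional
  fraction of points is removed with probability weighted toward low
  heights (pine-caterpillar feeding starts in the lower crown), and
  return intensity declines and grows more heterogeneous with DP.

The model is phenomenological: no radiative transfer, no terrain, no
crown-to-crown occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from defoliascan.damage import STAGE_DP_RANGE, STAGE_ORDER, stage_from_dp
from defoliascan.dataio import SpectraTable, TreePointCloud
from defoliascan.errors import InvalidInputError

DEFAULT_N_PER_CLASS = (103, 99, 82)


def default_wavelengths(n_bands: int = 145, lo: float = 400.0, hi: float = 1000.0):
    """Evenly spaced band centers; 145 points on [400, 1000] by default."""
    return np.linspace(lo, hi, n_bands)


@dataclass
class SpectraConfig:
    """Controls for the spectral generator.

    Effect sizes are reflectance change per unit DP (percent), so at
    DP = 50 the red-edge peak rises by ~50 * red_edge_gain.
    """

    n_per_class: tuple = DEFAULT_N_PER_CLASS
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    red_edge_gain: float = 0.0009  # reflectance per % DP at the red-edge bump peak
    nir_loss: float = 0.0011  # reflectance per % DP on the NIR plateau
    smooth_sd: float = 0.012  # sd of the band-correlated noise component
    smooth_scale: float = 50.0  # correlation length-scale, nm
    white_sd: float = 0.003  # sd of independent per-band noise
    seed: int = 0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.wavelengths) == 0 or np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("wavelength grid must be non-empty and increasing")
        if min(self.n_per_class) < 1:
            raise InvalidInputError("need >= 1 tree per class")
        for sd in (self.smooth_sd, self.white_sd):
            if sd < 0:
                raise InvalidInputError("noise sd must be >= 0")


@dataclass
class CrownConfig:
    """Controls for the crown point-cloud generator.

    The crown is a paraboloid of revolution (radius shrinking with
    height) sitting on a short stem; a small fraction of understory
    returns below 0.5 m is added so the height-threshold filter has
    something to remove. Intensity uses an 8-bit-like 0-255 scale.
    """

    crown_base: float = 1.0  # m, height of crown base above ground
    crown_depth: float = 6.0  # m, vertical extent of the live crown
    crown_radius: float = 1.5  # m, radius at the crown base
    crown_depth_sd: float = 1.0  # m, tree-to-tree crown depth variation
    crown_radius_sd: float = 0.25  # m, tree-to-tree radius variation
    crown_base_sd: float = 0.3  # m, tree-to-tree crown-base variation
    point_density: float = 120.0  # returns per m^2 of projected crown area
    bias_exponent: float = 2.0  # low-z weighting power for point removal (0 = uniform)
    understory_fraction: float = 0.03  # extra returns below 0.5 m
    intensity_mean: float = 160.0
    intensity_sd: float = 18.0
    intensity_tree_sd: float = 9.0  # per-tree random intensity offset (calibration,
    # incidence angle, canopy wetness); limits how informative per-tree means can be
    intensity_dp_slope: float = 0.9  # intensity units lost per % DP
    woody_offset: float = 45.0  # intensity deficit of exposed-wood returns
    woody_base_fraction: float = 0.05  # exposed-wood mixture weight at DP = 0
    woody_dp_slope: float = 0.004  # mixture-weight growth per % DP
    seed: int = 0

    def __post_init__(self):
        if self.point_density <= 0:
            raise InvalidInputError("point density must be > 0")
        if self.crown_depth <= 0 or self.crown_radius <= 0:
            raise InvalidInputError("crown dimensions must be > 0")
        if not 0 <= self.understory_fraction <= 1:
            raise InvalidInputError("understory fraction must be in [0, 1]")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def base_spectrum(wavelengths) -> np.ndarray:
    """Healthy-conifer reflectance template on an arbitrary grid.

    Green reflectance peak near 550 nm, chlorophyll absorption trough
    near 675 nm, red-edge ramp centered ~716 nm, NIR plateau, and a weak
    water-absorption dip near 975 nm. Values lie strictly inside (0, 1)
    and the NIR plateau (860 nm) exceeds the red trough (680 nm).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size == 0:
        raise InvalidInputError("empty wavelength grid")
    if np.any(wl < 350) or np.any(wl > 1100):
        raise InvalidInputError("wavelengths must lie within [350, 1100] nm")
    r = (
        0.035
        + 0.045 * np.exp(-(((wl - 550.0) / 28.0) ** 2))
        - 0.012 * np.exp(-(((wl - 675.0) / 22.0) ** 2))
        + 0.430 * _sigmoid((wl - 716.0) / 16.0)
        - 0.050 * np.exp(-(((wl - 975.0) / 45.0) ** 2))
    )
    return np.clip(r, 0.005, 0.95)


def _red_edge_weight(wl):
    return np.exp(-(((wl - 718.0) / 34.0) ** 2))


def _nir_weight(wl):
    return _sigmoid((wl - 840.0) / 30.0)


def apply_defoliation(base, dp: float, cfg: SpectraConfig, rng=None) -> np.ndarray:
    """Shift a spectrum according to defoliation percentage.

    Reflectance increases in the red-edge window and decreases on the
    NIR plateau, both linearly in DP; with ``rng`` given, smooth and
    white noise are added. Output is clipped to [0, 1]. With dp = 0 and
    no rng the input is returned unchanged.
    """
    if not np.isfinite(dp) or dp < 0 or dp > 100:
        raise InvalidInputError("dp must be within [0, 100]")
    wl = cfg.wavelengths
    base = np.asarray(base, dtype=float)
    if base.shape != wl.shape:
        raise InvalidInputError("base spectrum length must match the grid")
    out = base + dp * cfg.red_edge_gain * _red_edge_weight(wl)
    out = out - dp * cfg.nir_loss * _nir_weight(wl)
    if rng is not None:
        out = out + _smooth_noise(cfg, rng) + rng.normal(0.0, cfg.white_sd, wl.size)
    if dp == 0 and rng is None:
        return base.copy()
    return np.clip(out, 1e-4, 1.0)


def _smooth_chol(cfg: SpectraConfig):
    """Cholesky factor of the squared-exponential band correlation."""
    wl = cfg.wavelengths
    d = wl[:, None] - wl[None, :]
    corr = np.exp(-0.5 * (d / cfg.smooth_scale) ** 2)
    corr[np.diag_indices_from(corr)] += 1e-8
    return np.linalg.cholesky(corr)


def _smooth_noise(cfg: SpectraConfig, rng, chol=None):
    if cfg.smooth_sd == 0:
        return np.zeros(cfg.wavelengths.size)
    if chol is None:
        chol = _smooth_chol(cfg)
    return cfg.smooth_sd * (chol @ rng.standard_normal(cfg.wavelengths.size))


def generate_spectra_dataset(cfg: SpectraConfig | None = None) -> SpectraTable:
    """Generate the full synthetic spectra table (default 284 x 145).

    DP is drawn uniformly within each stage's interval (mild [5, 30],
    moderate (30, 50), severe [50, 90]); the stage label is recomputed
    from DP so the two are consistent by construction. Reproducible from
    ``cfg.seed``.
    """
    cfg = cfg or SpectraConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    base = base_spectrum(wl)
    chol = _smooth_chol(cfg) if cfg.smooth_sd > 0 else None
    rows, dps = [], []
    for stage, n in zip(STAGE_ORDER, cfg.n_per_class):
        lo, hi = STAGE_DP_RANGE[stage]
        dp_draw = rng.uniform(lo, hi, n)
        for dp in dp_draw:
            spec = base + dp * cfg.red_edge_gain * _red_edge_weight(wl)
            spec = spec - dp * cfg.nir_loss * _nir_weight(wl)
            spec = spec + _smooth_noise(cfg, rng, chol)
            spec = spec + rng.normal(0.0, cfg.white_sd, wl.size)
            rows.append(np.clip(spec, 1e-4, 1.0))
            dps.append(dp)
    dps = np.asarray(dps)
    n_total = len(rows)
    return SpectraTable(
        tree_id=np.array([f"t{i + 1:04d}" for i in range(n_total)], dtype=object),
        stage=stage_from_dp(dps),
        dp=dps,
        reflectance=np.vstack(rows),
        wavelengths=wl,
    )


def generate_planted_spectra(
    n_per_class=(30, 30, 30),
    planted_nm=(686.0, 759.0, 926.0),
    offsets=None,
    wavelengths=None,
    smooth_sd: float = 0.010,
    white_sd: float = 0.008,
    seed: int = 0,
) -> SpectraTable:
    """Spectra whose class signal lives only at chosen bands.

    Used for recovery experiments: every band carries the same healthy
    template plus classless noise, and class-dependent reflectance
    offsets are added only at the grid bands nearest ``planted_nm``.
    ``offsets[c][b]`` is the shift for class c (mild/moderate/severe) at
    planted band b; the default pattern makes no single band separate
    all three stages, so at least two planted bands are needed.
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    if offsets is None:
        d = 0.08
        offsets = np.array(
            [
                [0.0, 0.0, 0.0],  # mild: baseline
                [d, 0.0, -d / 2],  # moderate: red trough up, slight NIR drop
                [d, -d, -d],  # severe: red up, red-edge & NIR down
            ]
        )
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (3, len(planted_nm)):
        raise InvalidInputError("offsets must be (3 classes) x (n planted bands)")
    idx = [int(np.argmin(np.abs(wl - t))) for t in planted_nm]
    cfg = SpectraConfig(
        n_per_class=tuple(n_per_class),
        wavelengths=wl,
        red_edge_gain=0.0,
        nir_loss=0.0,
        smooth_sd=smooth_sd,
        white_sd=white_sd,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    base = base_spectrum(wl)
    chol = _smooth_chol(cfg) if smooth_sd > 0 else None
    rows, stages, dps = [], [], []
    dp_mid = {1: 15.0, 2: 40.0, 3: 70.0}
    for c, (stage, n) in enumerate(zip(STAGE_ORDER, n_per_class)):
        for _ in range(n):
            spec = base + _smooth_noise(cfg, rng, chol)
            spec = spec + rng.normal(0.0, white_sd, wl.size)
            for b, j in enumerate(idx):
                spec[j] += offsets[c, b]
            rows.append(np.clip(spec, 1e-4, 1.0))
            stages.append(stage)
            dps.append(dp_mid[stage])
    n_total = len(rows)
    return SpectraTable(
        tree_id=np.array([f"p{i + 1:04d}" for i in range(n_total)], dtype=object),
        stage=np.asarray(stages),
        dp=np.asarray(dps),
        reflectance=np.vstack(rows),
        wavelengths=wl,
    )


@dataclass
class CrownDraw:
    """One simulated crown: retained cloud plus removal bookkeeping."""

    cloud: TreePointCloud
    full_crown_count: int
    retained_crown_count: int
    removed_z: np.ndarray


def simulate_crown(dp: float, cfg: CrownConfig | None = None, tree_id: str = "tree",
                   seed: int | None = None) -> CrownDraw:
    """Sample a full crown, remove a DP-proportional low-biased fraction.

    Removal count is round(dp/100 * n_crown); removal probability is
    proportional to ((z_max - z) / range) ** bias_exponent, so low
    points go first when the exponent is positive and removal is uniform
    at exponent 0. Understory returns (z < 0.5 m) are kept out of the
    removal pool — they are ground/shrub echoes, not needles.
    """
    cfg = cfg or CrownConfig()
    if not np.isfinite(dp) or dp < 0 or dp > 100:
        raise InvalidInputError("dp must be within [0, 100]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    # tree-to-tree size variation (truncated to keep geometry sane)
    depth = max(1.0, rng.normal(cfg.crown_depth, cfg.crown_depth_sd))
    radius = max(0.3, rng.normal(cfg.crown_radius, cfg.crown_radius_sd))
    base = max(0.6, rng.normal(cfg.crown_base, cfg.crown_base_sd))
    n_crown = max(1, int(round(cfg.point_density * np.pi * radius**2)))
    # paraboloid crown: projected ring area falls linearly with height
    u = rng.uniform(0.0, 1.0, n_crown)
    t = 1.0 - np.sqrt(1.0 - u)  # inverse CDF of pdf ~ (1 - t)
    z = base + depth * t
    r = radius * np.sqrt(1.0 - t) * np.sqrt(rng.uniform(0.0, 1.0, n_crown))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_crown)
    x, y = r * np.cos(theta), r * np.sin(theta)

    n_remove = int(round(dp / 100.0 * n_crown))
    if n_remove > 0:
        zr = (z.max() - z) / max(z.max() - z.min(), 1e-12)
        w = zr**cfg.bias_exponent + 1e-9
        removed = rng.choice(n_crown, size=n_remove, replace=False, p=w / w.sum())
        keep = np.setdiff1d(np.arange(n_crown), removed)
        removed_z = z[removed]
    else:
        keep = np.arange(n_crown)
        removed_z = np.empty(0)
    x, y, z = x[keep], y[keep], z[keep]

    n_under = int(round(cfg.understory_fraction * n_crown))
    if n_under > 0:
        zu = rng.uniform(0.0, 0.5, n_under)
        ru = radius * np.sqrt(rng.uniform(0.0, 1.0, n_under))
        tu = rng.uniform(0.0, 2.0 * np.pi, n_under)
        x = np.concatenate([x, ru * np.cos(tu)])
        y = np.concatenate([y, ru * np.sin(tu)])
        z = np.concatenate([z, zu])

    mean_i = (
        cfg.intensity_mean
        - cfg.intensity_dp_slope * dp
        + rng.normal(0.0, cfg.intensity_tree_sd)
    )
    intensity = rng.normal(mean_i, cfg.intensity_sd, z.size)
    w_wood = min(1.0, cfg.woody_base_fraction + cfg.woody_dp_slope * dp)
    woody = rng.uniform(0.0, 1.0, z.size) < w_wood
    intensity[woody] -= cfg.woody_offset
    intensity = np.clip(intensity, 0.0, 255.0)

    cloud = TreePointCloud(tree_id, x, y, np.maximum(z, 0.0), intensity)
    return CrownDraw(
        cloud=cloud,
        full_crown_count=n_crown,
        retained_crown_count=len(keep),
        removed_z=removed_z,
    )


def generate_tree_cloud(dp: float, cfg: CrownConfig | None = None,
                        tree_id: str = "tree", seed: int | None = None) -> TreePointCloud:
    """Generate one defoliated crown point cloud (see :func:`simulate_crown`)."""
    return simulate_crown(dp, cfg, tree_id=tree_id, seed=seed).cloud


def generate_cloud_set(table: SpectraTable, cfg: CrownConfig | None = None) -> dict:
    """One cloud per tree of a spectra table, seeded per tree from cfg.seed."""
    cfg = cfg or CrownConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(table.n_trees) % (2**31)
    return {
        tid: generate_tree_cloud(dp, cfg, tree_id=str(tid), seed=int(s))
        for tid, dp, s in zip(table.tree_id, table.dp, seeds)
    }
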