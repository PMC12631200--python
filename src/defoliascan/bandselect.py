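"""Hyperspectral band selection: ISIC filtering, SPA, and chained ISIC-SPA.

ISIC (instability index between classes) scores each band by the ratio
of within-class spread to between-class mean separation, averaged over
the m(m-1)/2 unordered class pairs::

    ISIC_i = 2 / (m (m - 1)) * sum_{z<j} (S_z,i + S_j,i) / |m_z,i - m_j,i|

Lower is better; a pair with coincident class means makes the band
maximally unstable (ISIC = +inf). Adjacent-band jumps D_i =
|ISIC_i - ISIC_{i+1}| above a tuned threshold T mark bands for removal;
T is found by coarse-to-fine search maximizing 10-fold CV accuracy of a
random forest on the retained bands, preferring fewer bands among
near-ties.

SPA (successive projections algorithm) is a forward selector: each step
picks the band whose column has the largest residual norm after
orthogonal projection onto the span of the already-selected columns,
minimizing collinearity. Subset size is chosen from the CV-accuracy
curve (smallest size within tolerance of the best).

ISIC-SPA runs SPA on the ISIC-retained subset only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from defoliascan.classify_eval import RFConfig, cross_val_accuracy
from defoliascan.dataio import SpectraTable
from defoliascan.errors import DegenerateSelectionError, InvalidInputError


@dataclass
class CVConfig:
    """Cross-validation settings used inside band selection."""

    folds: int = 10
    seed: int = 0
    n_estimators: int = 100  # selection-time forest; final models use more
    tol: float = 0.005  # accuracy slack for "fewest bands" tie-breaking

    def rf(self) -> RFConfig:
        return RFConfig(n_estimators=self.n_estimators, random_state=self.seed)


@dataclass
class GridConfig:
    """Threshold-search grid: coarse pass then x10-finer local passes."""

    n_coarse: int = 8
    refine_rounds: int = 2
    refine_span: int = 5  # points on each side of the incumbent per round

    def __post_init__(self):
        if self.n_coarse < 1 or self.refine_rounds < 0 or self.refine_span < 1:
            raise InvalidInputError("invalid threshold grid configuration")


@dataclass
class ISICProfile:
    """Per-band ISIC values, adjacent jumps D, threshold, retained mask."""

    isic: np.ndarray
    d: np.ndarray
    threshold: float
    retained: np.ndarray  # boolean mask over bands


@dataclass
class BandSelectionResult:
    """Outcome of one selection method, with its accuracy-vs-size curve."""

    method: str
    band_indices: list
    wavelengths: list
    accuracy_curve: list  # (size or threshold, mean CV accuracy) pairs
    chosen_size: int
    threshold: float | None = None
    threshold_curve: list | None = None
    n_retained_by_isic: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "band_indices": [int(i) for i in self.band_indices],
            "wavelengths": [float(w) for w in self.wavelengths],
            "accuracy_curve": [[float(a), float(b)] for a, b in self.accuracy_curve],
            "chosen_size": int(self.chosen_size),
            "threshold": None if self.threshold is None else float(self.threshold),
            "threshold_curve": None
            if self.threshold_curve is None
            else [[float(a), float(b), int(c)] for a, b, c in self.threshold_curve],
            "n_retained_by_isic": self.n_retained_by_isic,
        }


def _as_matrix(spectra, labels):
    if isinstance(spectra, SpectraTable):
        return spectra.reflectance, (spectra.stage if labels is None else np.asarray(labels))
    if labels is None:
        raise InvalidInputError("labels required when spectra is a plain matrix")
    return np.asarray(spectra, dtype=float), np.asarray(labels)


def isic_values(spectra, labels=None) -> np.ndarray:
    """Per-band ISIC vector; +inf where a class pair has coincident means."""
    X, y = _as_matrix(spectra, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise InvalidInputError("ISIC needs >= 2 classes")
    means, sds = [], []
    for cls in classes:
        rows = X[y == cls]
        if rows.shape[0] < 2:
            raise InvalidInputError(f"class {cls!r} has fewer than 2 samples")
        means.append(rows.mean(axis=0))
        sds.append(rows.std(axis=0, ddof=1))
    means = np.vstack(means)
    sds = np.vstack(sds)
    m = len(classes)
    total = np.zeros(X.shape[1])
    for z in range(m - 1):
        for j in range(z + 1, m):
            sep = np.abs(means[z] - means[j])
            spread = sds[z] + sds[j]
            # scale-invariant degeneracy check: coincident class means
            # make the band maximally unstable regardless of spread
            ref = np.maximum(np.maximum(np.abs(means[z]), np.abs(means[j])), spread)
            degenerate = sep <= 1e-12 * ref
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(degenerate, np.inf, spread / np.where(degenerate, 1.0, sep))
            total = total + term
    n_pairs = m * (m - 1) / 2
    return total / n_pairs


def di_series(isic) -> np.ndarray:
    """Adjacent-band instability jumps D_i = |ISIC_i - ISIC_{i+1}|.

    +inf entries in ISIC propagate to +inf on both adjacent D entries.
    """
    isic = np.asarray(isic, dtype=float)
    if isic.size < 2:
        raise InvalidInputError("need >= 2 ISIC values for D series")
    d = np.abs(np.diff(isic))
    inf_pair = np.isinf(isic[:-1]) | np.isinf(isic[1:])
    d[inf_pair] = np.inf
    return d


def retained_mask(d, threshold: float) -> np.ndarray:
    """Boolean retention mask over B bands from the D series.

    Band i (i < B-1) is removed iff D_i > T; the last band is judged by
    its left difference D_{B-1}.
    """
    d = np.asarray(d, dtype=float)
    if threshold < 0:
        raise InvalidInputError("threshold must be >= 0")
    mask = np.empty(d.size + 1, dtype=bool)
    mask[:-1] = ~(d > threshold)
    mask[-1] = not (d[-1] > threshold)
    return mask


def filter_by_threshold(profile, threshold: float) -> np.ndarray:
    """Retained band indices under threshold T; errors if none survive."""
    d = profile.d if isinstance(profile, ISICProfile) else np.asarray(profile)
    mask = retained_mask(d, threshold)
    if not mask.any():
        raise DegenerateSelectionError(f"threshold {threshold} removes every band")
    return np.flatnonzero(mask)


def _cv_cached(cache, X, y, mask_key, cols, cv_cfg: CVConfig) -> float:
    if mask_key not in cache:
        cache[mask_key] = cross_val_accuracy(
            X[:, cols], y, folds=cv_cfg.folds, rf_cfg=cv_cfg.rf(), seed=cv_cfg.seed
        )
    return cache[mask_key]


@dataclass
class ThresholdSearchResult:
    threshold: float
    retained: np.ndarray  # indices
    curve: list  # (threshold, cv accuracy, n retained)
    profile: ISICProfile


def optimize_threshold(spectra, labels=None, cv_cfg: CVConfig | None = None,
                       grid_cfg: GridConfig | None = None) -> ThresholdSearchResult:
    """Coarse-to-fine search for the D-threshold maximizing CV accuracy.

    A coarse grid spans [0, max finite D]; each refinement round shrinks
    the step x10 around the incumbent. Among thresholds within ``tol``
    of the best accuracy the one retaining fewest bands wins (then the
    smallest threshold).
    """
    cv_cfg = cv_cfg or CVConfig()
    grid_cfg = grid_cfg or GridConfig()
    X, y = _as_matrix(spectra, labels)
    isic = isic_values(X, y)
    d = di_series(isic)
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        raise DegenerateSelectionError("no finite D values; threshold search impossible")
    d_max = float(finite.max())

    cache: dict = {}
    evaluated: dict = {}  # threshold -> (acc, n_retained)

    def evaluate(t: float):
        t = float(max(t, 0.0))
        if t in evaluated:
            return
        mask = retained_mask(d, t)
        if not mask.any():
            evaluated[t] = (-np.inf, 0)
            return
        cols = np.flatnonzero(mask)
        acc = _cv_cached(cache, X, y, mask.tobytes(), cols, cv_cfg)
        evaluated[t] = (acc, int(mask.sum()))

    if grid_cfg.n_coarse == 1:
        grid = np.array([0.0])
        step = d_max if d_max > 0 else 1.0
    else:
        grid = np.linspace(0.0, d_max, grid_cfg.n_coarse)
        step = grid[1] - grid[0]
    for t in grid:
        evaluate(t)

    def incumbent():
        best_acc = max(acc for acc, _ in evaluated.values())
        near = [
            (n, t)
            for t, (acc, n) in evaluated.items()
            if acc >= best_acc - cv_cfg.tol and np.isfinite(acc)
        ]
        n_min, t_star = min(near)
        return t_star

    for _ in range(grid_cfg.refine_rounds):
        step /= 10.0
        center = incumbent()
        for k in range(-grid_cfg.refine_span, grid_cfg.refine_span + 1):
            t = center + k * step
            if 0.0 <= t <= d_max:
                evaluate(t)

    if all(not np.isfinite(acc) for acc, _ in evaluated.values()):
        raise DegenerateSelectionError("objective failed at every grid point")
    t_star = incumbent()
    mask = retained_mask(d, t_star)
    curve = sorted((t, acc, n) for t, (acc, n) in evaluated.items() if np.isfinite(acc))
    profile = ISICProfile(isic=isic, d=d, threshold=t_star, retained=mask)
    return ThresholdSearchResult(
        threshold=t_star, retained=np.flatnonzero(mask), curve=curve, profile=profile
    )


def spa_chain(X, start: int, k_max: int, tol: float = 1e-10) -> list:
    """Forward SPA chain from one start band.

    At each step the column with the largest residual norm (after
    projecting out the span of the chain so far) is appended; the chain
    stops early when every residual norm falls below ``tol`` relative to
    the largest initial column norm, so selected columns stay linearly
    independent. Ties break to the lowest index.
    """
    X = np.array(X, dtype=float)
    n, B = X.shape
    if not 0 <= start < B:
        raise InvalidInputError(f"start band {start} outside [0, {B})")
    if k_max < 1:
        raise InvalidInputError("k_max must be >= 1")
    k_max = min(k_max, B, n)
    scale = max(np.sqrt((X**2).sum(axis=0)).max(), 1.0)
    chain = [start]
    R = X.copy()
    for _ in range(k_max - 1):
        r_sel = R[:, chain[-1]].copy()
        nrm2 = float(r_sel @ r_sel)
        if nrm2 <= (tol * scale) ** 2:
            chain.pop()
            break
        R -= np.outer(r_sel, r_sel @ R) / nrm2
        norms = np.sqrt((R**2).sum(axis=0))
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= tol * scale:
            break
        chain.append(nxt)
    return chain


def _resolve_starts(B: int, starts) -> list:
    if starts is None:
        return list(range(B))
    if isinstance(starts, (int, np.integer)):
        k = min(int(starts), B)
        return sorted(set(np.linspace(0, B - 1, k).round().astype(int).tolist()))
    return sorted(set(int(s) for s in starts))


def _prefix_curve(Xc, y, chains, k_max, cv_cfg):
    """Best CV accuracy per subset size over all chain prefixes."""
    cache: dict = {}
    curve, best_sets = [], {}
    for k in range(1, k_max + 1):
        best_acc, best_chain = -np.inf, None
        seen = set()
        for start in sorted(chains):
            chain = chains[start]
            if len(chain) < k:
                continue
            key = frozenset(chain[:k])
            if key in seen:
                continue
            seen.add(key)
            acc = _cv_cached(cache, Xc, y, key, list(chain[:k]), cv_cfg)
            if acc > best_acc:
                best_acc, best_chain = acc, list(chain[:k])
        if best_chain is None:
            break
        curve.append((k, best_acc))
        best_sets[k] = best_chain
    return curve, best_sets


def spa_select(spectra, labels=None, cv_cfg: CVConfig | None = None,
               k_max: int = 10, starts=None, wavelengths=None) -> BandSelectionResult:
    """SPA with CV-accuracy subset sizing.

    Chains are launched from every band (or a subsample of ``starts``);
    for each size k the best prefix by stratified 10-fold CV accuracy
    defines the curve, and the chosen size is the smallest k whose
    accuracy is within ``cv_cfg.tol`` of the curve maximum.
    """
    cv_cfg = cv_cfg or CVConfig()
    X, y = _as_matrix(spectra, labels)
    if wavelengths is None and isinstance(spectra, SpectraTable):
        wavelengths = spectra.wavelengths
    Xc = X - X.mean(axis=0)
    B = X.shape[1]
    k_max = min(k_max, B, X.shape[0] - 1)
    chains = {s: spa_chain(Xc, s, k_max) for s in _resolve_starts(B, starts)}
    curve, best_sets = _prefix_curve(X, y, chains, k_max, cv_cfg)
    if not curve:
        raise DegenerateSelectionError("no SPA chain produced a scorable subset")
    best_acc = max(acc for _, acc in curve)
    chosen_k = next(k for k, acc in curve if acc >= best_acc - cv_cfg.tol)
    indices = best_sets[chosen_k]
    wl = [float(wavelengths[i]) for i in indices] if wavelengths is not None else []
    return BandSelectionResult(
        method="spa",
        band_indices=[int(i) for i in indices],
        wavelengths=wl,
        accuracy_curve=curve,
        chosen_size=chosen_k,
    )


def isic_select(spectra, labels=None, cv_cfg: CVConfig | None = None,
                grid_cfg: GridConfig | None = None, wavelengths=None) -> BandSelectionResult:
    """ISIC-only selection: the bands retained by the tuned D-threshold."""
    X, y = _as_matrix(spectra, labels)
    if wavelengths is None and isinstance(spectra, SpectraTable):
        wavelengths = spectra.wavelengths
    search = optimize_threshold(X, y, cv_cfg=cv_cfg, grid_cfg=grid_cfg)
    idx = search.retained
    wl = [float(wavelengths[i]) for i in idx] if wavelengths is not None else []
    curve = [(n, acc) for _, acc, n in search.curve]
    return BandSelectionResult(
        method="isic",
        band_indices=[int(i) for i in idx],
        wavelengths=wl,
        accuracy_curve=curve,
        chosen_size=len(idx),
        threshold=search.threshold,
        threshold_curve=search.curve,
        n_retained_by_isic=len(idx),
    )


def isic_spa_select(spectra, labels=None, cv_cfg: CVConfig | None = None,
                    grid_cfg: GridConfig | None = None, k_max: int = 10,
                    starts=None, wavelengths=None,
                    threshold: float | None = None) -> BandSelectionResult:
    """Chained selection: SPA restricted to the ISIC-retained bands.

    ``threshold`` overrides the search (useful for analysis); +inf
    reduces the method to plain SPA on all bands.
    """
    cv_cfg = cv_cfg or CVConfig()
    X, y = _as_matrix(spectra, labels)
    if wavelengths is None and isinstance(spectra, SpectraTable):
        wavelengths = spectra.wavelengths
    if threshold is None:
        search = optimize_threshold(X, y, cv_cfg=cv_cfg, grid_cfg=grid_cfg)
        t_star, retained, t_curve = search.threshold, search.retained, search.curve
    else:
        d = di_series(isic_values(X, y))
        retained = filter_by_threshold(d, threshold)
        t_star, t_curve = threshold, None
    if len(retained) < 2:
        raise DegenerateSelectionError(
            f"ISIC stage retained {len(retained)} band(s); SPA needs >= 2"
        )
    sub = spa_select(
        X[:, retained], y, cv_cfg=cv_cfg, k_max=min(k_max, len(retained)),
        starts=starts,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths)[retained],
    )
    indices = [int(retained[i]) for i in sub.band_indices]
    return BandSelectionResult(
        method="isic-spa",
        band_indices=indices,
        wavelengths=sub.wavelengths,
        accuracy_curve=sub.accuracy_curve,
        chosen_size=sub.chosen_size,
        threshold=t_star,
        threshold_curve=t_curve,
        n_retained_by_isic=len(retained),
    )
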