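"""Wavelength selection: CARS, SPA and Random Frog over PLSR scoring.

SWIR cubes carry hundreds of strongly correlated bands of which only a
few discriminate crack from intact shell. Three complementary selectors
are provided, all scoring candidate subsets by the root-mean-square error
of Monte-Carlo cross-validated PLS regression (RMSECV) of the binary
crack label on the pixel spectra:

* **CARS** (Competitive Adaptive Reweighted Sampling) — iterative
  elimination driven by normalized PLS coefficient weights
  ``w_j = |β_j| / Σ_i |β_i|`` with an exponentially decaying retention
  ratio; keeps the subset with minimal RMSECV across iterations.
* **SPA** (Successive Projections Algorithm) — forward selection that
  repeatedly adds the band with the largest residual after orthogonal
  projection onto the span of the already-selected bands,
  ``P x_j = x_j − X_s (X_sᵀ X_s)⁻¹ X_sᵀ x_j``, minimizing collinearity.
* **Random Frog** — a simulated-annealing-flavoured stochastic subset
  search with Metropolis acceptance
  ``P = min(1, exp(−(E(S′) − E(S))/T))``; bands are ranked by their
  frequency in accepted subsets and thresholded.

The binary label is regressed directly (PLS-DA style); RMSE is the
subset energy throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .core import SpectralCube
from .errors import ParameterError
from .io_envi import log
from .preprocess import SpectraMatrix

DEFAULT_N_LATENT = 5
DEFAULT_MC_DRAWS = 30
DEFAULT_MC_TEST_FRACTION = 0.2

METHODS = ("CARS", "SPA", "RF", "full")


@dataclass
class BandSubset:
    """Selected band indices plus per-method diagnostics."""

    indices: np.ndarray
    method: str = "full"
    wavelengths_nm: np.ndarray | None = None
    rmsecv_trace: np.ndarray | None = None       # CARS: RMSECV per iteration
    selection_probability: np.ndarray | None = None  # RF: per-band frequency
    rmse_by_count: np.ndarray | None = None      # SPA: RMSE per prefix size

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.intp))
        if idx.size == 0:
            raise ParameterError("band subset is empty")
        if idx.min() < 0:
            raise ParameterError("band indices must be non-negative")
        if self.method not in METHODS:
            raise ParameterError(f"unknown selection method {self.method!r}")
        self.indices = idx

    @property
    def n_bands(self) -> int:
        return int(self.indices.size)

    def to_json(self, path) -> Path:
        payload = {
            "method": self.method,
            "indices": self.indices.tolist(),
            "n_bands": self.n_bands,
        }
        if self.wavelengths_nm is not None:
            payload["wavelengths_nm"] = np.round(self.wavelengths_nm, 4).tolist()
        for key in ("rmsecv_trace", "selection_probability", "rmse_by_count"):
            val = getattr(self, key)
            if val is not None:
                payload[key] = np.round(np.asarray(val, float), 6).tolist()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "BandSubset":
        payload = json.loads(Path(path).read_text())
        return cls(
            indices=np.asarray(payload["indices"], dtype=np.intp),
            method=payload.get("method", "full"),
            wavelengths_nm=(np.asarray(payload["wavelengths_nm"])
                            if "wavelengths_nm" in payload else None),
            rmsecv_trace=(np.asarray(payload["rmsecv_trace"])
                          if "rmsecv_trace" in payload else None),
            selection_probability=(np.asarray(payload["selection_probability"])
                                   if "selection_probability" in payload else None),
            rmse_by_count=(np.asarray(payload["rmse_by_count"])
                           if "rmse_by_count" in payload else None),
        )


@dataclass
class CarsConfig:
    n_iterations: int = 50
    sampling_ratio: float = 0.8
    n_latent: int = DEFAULT_N_LATENT
    decay_a: float | None = None   # derived from B and n_iterations when None
    decay_k: float | None = None
    min_bands: int = 2             # argmin restricted to subsets >= this size
    max_bands: int | None = None   # ... and <= this size (None = unbounded)
    mc_draws: int = DEFAULT_MC_DRAWS
    mc_test_fraction: float = DEFAULT_MC_TEST_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.sampling_ratio <= 1):
            raise ParameterError("sampling_ratio must be in (0, 1]")
        if self.n_iterations < 2:
            raise ParameterError("n_iterations must be >= 2")


@dataclass
class RfConfig:
    n_iterations: int = 800
    temperature_init: float = 0.05
    temperature_decay: float = 0.95
    threshold: float = 0.2
    n_latent: int = DEFAULT_N_LATENT
    initial_size: int = 10
    mc_draws: int = 8
    mc_test_fraction: float = DEFAULT_MC_TEST_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature_init <= 0:
            raise ParameterError("temperature_init must be positive")
        if not (0 < self.threshold < 1):
            raise ParameterError("threshold must be in (0, 1)")


def plsr_fit(X: np.ndarray, y: np.ndarray, n_latent: int = DEFAULT_N_LATENT,
             warn_on_cap: bool = True) -> np.ndarray:
    """PLS regression coefficients β (length B) of y on column-centered X.

    Components are capped at ``min(N-1, B)``; a rank-deficiency warning is
    logged if the cap bites. A constant response yields β = 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, b = X.shape
    if np.ptp(y) == 0:
        return np.zeros(b)
    cap = max(1, min(n - 1, b))
    if n_latent > cap:
        if warn_on_cap:
            log.warning("plsr_fit: reducing components %d -> %d", n_latent, cap)
        n_latent = cap
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=n_latent, scale=False)
        model.fit(X, y)
    return np.ravel(model.coef_)


def _pls_model(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSRegression:
    cap = max(1, min(X.shape[0] - 1, X.shape[1], n_latent))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PLSRegression(n_components=cap, scale=False)
        model.fit(X, y)
    return model


def cars_weights(beta: np.ndarray) -> np.ndarray:
    """Normalized absolute PLS coefficients: w_j = |β_j| / Σ_i |β_i|."""
    beta = np.asarray(beta, dtype=np.float64).ravel()
    total = np.abs(beta).sum()
    if total == 0:
        raise ParameterError("all-zero coefficient vector has no weights")
    return np.abs(beta) / total


def rmsecv(M: SpectraMatrix, indices, n_latent: int = DEFAULT_N_LATENT,
           n_draws: int = DEFAULT_MC_DRAWS,
           test_fraction: float = DEFAULT_MC_TEST_FRACTION,
           seed: int = 0) -> float:
    """Monte-Carlo cross-validated RMSE of PLSR restricted to ``indices``.

    Each draw holds out ``test_fraction`` of the samples at random; the
    returned value is the RMSE pooled over all held-out predictions.
    Deterministic under ``seed``.
    """
    idx = np.asarray(indices, dtype=np.intp)
    if idx.size == 0:
        raise ParameterError("band subset is empty")
    X, y = M.X[:, idx], M.y.astype(np.float64)
    n = X.shape[0]
    n_test = max(1, int(round(test_fraction * n)))
    if n - n_test < 2:
        raise ParameterError("too few samples for the requested split")
    rng = np.random.default_rng(seed)
    sq_errors = []
    for _ in range(n_draws):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        model = _pls_model(X[train], y[train], n_latent)
        pred = np.ravel(model.predict(X[test]))
        sq_errors.append((pred - y[test]) ** 2)
    return float(np.sqrt(np.mean(np.concatenate(sq_errors))))


def _cars_decay_constants(b: int, n_iter: int) -> tuple[float, float]:
    """Exponential decay r_i = a e^{-k i} with r_1 = 1 and r_N = 2/b."""
    if b <= 2:
        return 1.0, 0.0
    k = math.log(b / 2.0) / (n_iter - 1)
    return math.exp(k), k


def cars_select(M: SpectraMatrix, cfg: CarsConfig | None = None) -> BandSubset:
    """Competitive Adaptive Reweighted Sampling band selection.

    Per iteration: a Monte-Carlo draw of samples fits PLSR on the bands
    still in play; the top ``r_i · B`` bands by weight survive enforced
    elimination, then adaptive reweighted sampling (weighted draw with
    replacement) thins them further. The subset whose RMSECV is minimal
    over all iterations is returned along with the full RMSECV trace.
    """
    cfg = cfg or CarsConfig()
    rng = np.random.default_rng(cfg.seed)
    X, y = M.X, M.y.astype(np.float64)
    n, b = X.shape
    if b == 1:
        trace = np.array([rmsecv(M, [0], cfg.n_latent, cfg.mc_draws,
                                 cfg.mc_test_fraction, cfg.seed)])
        return BandSubset(indices=np.array([0]), method="CARS",
                          wavelengths_nm=M.band_grid.centers_nm.copy(),
                          rmsecv_trace=trace)

    a, k = (cfg.decay_a, cfg.decay_k)
    if a is None or k is None:
        a, k = _cars_decay_constants(b, cfg.n_iterations)

    n_draw = max(2, math.ceil(cfg.sampling_ratio * n))
    retained = np.arange(b)
    subsets: list[np.ndarray] = []
    trace: list[float] = []

    for it in range(1, cfg.n_iterations + 1):
        sample = rng.choice(n, size=n_draw, replace=False)
        beta = plsr_fit(X[np.ix_(sample, retained)], y[sample], cfg.n_latent,
                        warn_on_cap=False)
        if np.all(beta == 0):
            w = np.full(retained.size, 1.0 / retained.size)
        else:
            w = cars_weights(beta)

        keep = max(2, int(round(a * math.exp(-k * it) * b)))
        keep = min(keep, retained.size)
        # Enforced elimination: stable top-k by weight, ties to lower index.
        order = np.lexsort((retained, -w))
        pos = np.sort(order[:keep])
        survivors = retained[pos]
        w_surv = w[pos]

        # Adaptive reweighted sampling among the survivors.
        if survivors.size > 2 and w_surv.sum() > 0:
            p = w_surv / w_surv.sum()
            drawn = rng.choice(survivors, size=survivors.size, replace=True, p=p)
            sampled = np.unique(drawn)
            if sampled.size >= 2:
                survivors = sampled

        retained = survivors
        subsets.append(retained.copy())
        trace.append(rmsecv(M, retained, cfg.n_latent, cfg.mc_draws,
                            cfg.mc_test_fraction, cfg.seed + it))
        if retained.size <= 1:
            break

    hi = cfg.max_bands if cfg.max_bands is not None else max(
        s.size for s in subsets)
    eligible = [i for i, s in enumerate(subsets)
                if cfg.min_bands <= s.size <= hi]
    if not eligible:
        # The decay schedule skipped the requested size range: fall back to
        # the iterations whose subset size is closest to it.
        def dist(sz):
            return max(cfg.min_bands - sz, sz - hi, 0)
        best_dist = min(dist(s.size) for s in subsets)
        eligible = [i for i, s in enumerate(subsets)
                    if dist(s.size) == best_dist]
    best = min(eligible, key=lambda i: trace[i])
    chosen = subsets[best]
    return BandSubset(
        indices=chosen, method="CARS",
        wavelengths_nm=M.band_grid.centers_nm[np.sort(chosen)],
        rmsecv_trace=np.asarray(trace),
    )


def spa_project(xj: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    """Residual of ``xj`` after orthogonal projection onto span(Xs)."""
    xj = np.asarray(xj, dtype=np.float64).ravel()
    Xs = np.atleast_2d(np.asarray(Xs, dtype=np.float64))
    if Xs.shape[0] != xj.size:
        Xs = Xs.T
    gram = Xs.T @ Xs
    try:
        coeffs = np.linalg.solve(gram, Xs.T @ xj)
    except np.linalg.LinAlgError:
        log.warning("spa_project: singular Gram matrix, using pseudo-inverse")
        coeffs = np.linalg.pinv(gram) @ (Xs.T @ xj)
    return xj - Xs @ coeffs


def spa_select(M: SpectraMatrix, max_bands: int = 20,
               n_latent: int = DEFAULT_N_LATENT,
               mc_draws: int = DEFAULT_MC_DRAWS,
               mc_test_fraction: float = DEFAULT_MC_TEST_FRACTION,
               seed: int = 0) -> BandSubset:
    """Successive Projections Algorithm forward band selection.

    Builds a chain starting at the largest-norm band column, each step
    adding the band with maximal orthogonal-projection residual norm; the
    chain prefix with minimal RMSECV is returned (``rmse_by_count`` holds
    the RMSE for every prefix size).
    """
    if max_bands < 1:
        raise ParameterError("max_bands must be >= 1")
    X = M.X
    b = X.shape[1]
    max_bands = min(max_bands, b)

    chain = [int(np.argmax(np.linalg.norm(X, axis=0)))]
    residuals = X.copy()
    # Deflate iteratively: after adding a band, project all columns onto the
    # orthogonal complement of its residual direction (Gram-Schmidt sweep).
    v = residuals[:, chain[0]].copy()
    while len(chain) < max_bands:
        vn = v / (v @ v)
        residuals = residuals - np.outer(v, vn @ residuals)
        norms = np.linalg.norm(residuals, axis=0)
        norms[chain] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-10:
            break  # remaining bands are numerically in the selected span
        chain.append(nxt)
        v = residuals[:, nxt].copy()

    rmse_by_count = np.array([
        rmsecv(M, sorted(chain[:size]), n_latent, mc_draws,
               mc_test_fraction, seed)
        for size in range(1, len(chain) + 1)
    ])
    best_size = int(np.argmin(rmse_by_count)) + 1
    chosen = np.sort(np.asarray(chain[:best_size], dtype=np.intp))
    return BandSubset(
        indices=chosen, method="SPA",
        wavelengths_nm=M.band_grid.centers_nm[chosen],
        rmse_by_count=rmse_by_count,
    )


def rf_acceptance(e_current: float, e_candidate: float, temperature: float
                  ) -> float:
    """Metropolis acceptance: min(1, exp(−(E(S′) − E(S)) / T))."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    if e_candidate <= e_current:
        return 1.0  # improvements (and ties) are always accepted
    return float(math.exp(-(e_candidate - e_current) / temperature))


def random_frog_select(M: SpectraMatrix, cfg: RfConfig | None = None
                       ) -> BandSubset:
    """Random Frog stochastic subset search.

    A random walk over band subsets perturbs the current subset (replace,
    add or remove one band with equal probability, never emptying it),
    scores the candidate by RMSECV and accepts via the Metropolis rule at
    a geometrically decaying temperature. Bands whose frequency in the
    visited (accepted) subsets exceeds ``cfg.threshold`` are returned.

    The chain starts from the ``initial_size`` bands most correlated
    (in absolute value) with the label, which shortens burn-in compared
    with a uniform random initial subset.
    """
    cfg = cfg or RfConfig()
    rng = np.random.default_rng(cfg.seed)
    b = M.n_bands
    if b < 2:
        raise ParameterError("Random Frog needs at least 2 bands")

    size0 = min(max(2, cfg.initial_size), b)
    yc = M.y - M.y.mean()
    xc = M.X - M.X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(xc.T @ yc) / (np.linalg.norm(xc, axis=0)
                                    * np.linalg.norm(yc) + 1e-12)
    current = np.sort(np.argsort(-corr, kind="stable")[:size0])
    e_current = rmsecv(M, current, cfg.n_latent, cfg.mc_draws,
                       cfg.mc_test_fraction, cfg.seed)
    counts = np.zeros(b, dtype=np.int64)
    temperature = cfg.temperature_init

    for it in range(cfg.n_iterations):
        candidate = _rf_perturb(current, b, rng)
        e_candidate = rmsecv(M, candidate, cfg.n_latent, cfg.mc_draws,
                             cfg.mc_test_fraction, cfg.seed + 1 + it)
        if rng.random() < rf_acceptance(e_current, e_candidate, temperature):
            current, e_current = candidate, e_candidate
        counts[current] += 1
        temperature *= cfg.temperature_decay

    prob = counts / cfg.n_iterations
    chosen = np.flatnonzero(prob > cfg.threshold)
    if chosen.size == 0:
        log.warning("random_frog_select: no band above threshold %.2f, "
                    "returning the most frequent band", cfg.threshold)
        chosen = np.array([int(np.argmax(prob))])
    return BandSubset(
        indices=chosen, method="RF",
        wavelengths_nm=M.band_grid.centers_nm[chosen],
        selection_probability=prob,
    )


def _rf_perturb(subset: np.ndarray, b: int, rng: np.random.Generator
                ) -> np.ndarray:
    """One replace/add/remove move; never empties the subset."""
    subset = np.asarray(subset)
    outside = np.setdiff1d(np.arange(b), subset, assume_unique=False)
    moves = ["replace", "add", "remove"]
    if outside.size == 0:
        moves = ["remove"] if subset.size > 1 else ["replace"]
    if subset.size <= 1 and "remove" in moves:
        moves.remove("remove")
    move = moves[rng.integers(len(moves))]
    if move == "replace" and outside.size:
        out = subset[rng.integers(subset.size)]
        new = outside[rng.integers(outside.size)]
        return np.sort(np.append(subset[subset != out], new))
    if move == "add" and outside.size:
        new = outside[rng.integers(outside.size)]
        return np.sort(np.append(subset, new))
    out = subset[rng.integers(subset.size)]
    return subset[subset != out]


def apply_subset(cube: SpectralCube, subset: BandSubset) -> SpectralCube:
    """Restrict a cube to the selected bands (grid subset accordingly)."""
    idx = subset.indices
    if idx.max() >= cube.bands:
        raise ParameterError(
            f"band index {int(idx.max())} out of range for {cube.bands}-band cube"
        )
    return SpectralCube(
        data=np.ascontiguousarray(cube.data[:, :, idx]),
        grid=cube.grid.subset(idx),
        kind=cube.kind,
        provenance=(cube.provenance + f" | {subset.method} {idx.size} bands").strip(" |"),
    )


def dimensionality_reduction_pct(n_selected: int, n_total: int) -> float:
    """Percentage of the band axis removed by selection."""
    if n_total <= 0 or n_selected < 0 or n_selected > n_total:
        raise ParameterError("invalid band counts")
    return 100.0 * (1.0 - n_selected / n_total)
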