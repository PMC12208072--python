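"""Brownian-motion data augmentation for nanopore current traces.

A measured translocation event is a fixed-length array of normalized ionic
current.  Thermal forces on the translocating DNA perturb its instantaneous
speed, so the *same* molecule measured again would have produced a trace whose
features arrive slightly earlier or later — non-uniformly along the trace.
The augmentation emulates this by resampling a real trace ``X[n]`` at virtual
positions given by a drifted Gaussian random walk,

    i0[0] = 0,    i0[n] = i0[n-1] + Z[n],    Z[n] ~ N(1, sigma),

clamping the walk into the valid index range and linearly interpolating::

    Y[n] = X[floor(i0[n])] + frac(i0[n]) * (X[ceil(i0[n])] - X[floor(i0[n])])

With ``sigma = 0`` the walk is the identity index sequence and the augmented
trace equals the original bit-for-bit.

The module also provides the classic trace augmentations (uniform stretch,
additive noise, magnitude scaling, baseline shift), the batch driver applying
them per epoch, and the *equivalent uniform stretch* estimator used as a
control: the empirical standard deviation of the relative event-length change
induced by the Brownian walk, which parameterizes a global stretch with the
same length variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "IndexSequence",
    "AugmentationConfig",
    "draw_indexes",
    "interpolate_trace",
    "brownian_augment",
    "uniform_stretch",
    "add_noise",
    "scale_magnitude",
    "shift_baseline",
    "equivalent_stretch_std",
    "augment_batch",
    "BrownianAugmenter",
    "TraceAugmenter",
]


def _as_rng(seed) -> Generator:
    """Accept an int seed, a SeedSequence, a Generator or None."""
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


@dataclass(frozen=True)
class IndexSequence:
    """An augmenting index walk.

    Attributes
    ----------
    values : ndarray
        The walk clamped into ``[0, L-1]`` — negative positions are replaced
        by 0 (the walk "waits" at the trace start) and positions past the end
        hold the final sample (the zero-padding tail of a real trace).
    sigma : float
        The step standard deviation the walk was drawn with.
    raw_values : ndarray
        The walk before clamping; its moments follow the Brownian law
        ``E[i0[n]] = n``, ``Var[i0[n]] = n * sigma**2``.
    """

    values: np.ndarray
    sigma: float
    raw_values: np.ndarray

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.values)


def draw_indexes(L: int, sigma: float, seed=None) -> IndexSequence:
    """Draw the augmenting index walk ``i0[n]`` for a length-``L`` trace.

    ``i0[0] = 0`` and each step advances by ``Z[n] ~ N(1, sigma)``; the walk
    is then clamped into ``[0, L-1]``.  ``sigma = 0`` yields exactly
    ``[0, 1, ..., L-1]``.
    """
    if L < 2:
        raise ValueError(f"L must be >= 2, got {L}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = _as_rng(seed)
    raw = np.empty(L, dtype=float)
    raw[0] = 0.0
    np.cumsum(rng.normal(1.0, sigma, size=L - 1), out=raw[1:])
    values = np.clip(raw, 0.0, float(L - 1))
    return IndexSequence(values=values, sigma=float(sigma), raw_values=raw)


def interpolate_trace(X, indexes) -> np.ndarray:
    """Linearly interpolate trace ``X`` at the augmenting indexes.

    ``Y[n] = X[floor(i0[n])] + (i0[n] - floor(i0[n])) * (X[ceil(i0[n])] -
    X[floor(i0[n])])``.  Indexes must already lie in ``[0, L-1]``; range
    clamping is :func:`draw_indexes`'s responsibility.
    """
    X = np.asarray(X, dtype=float)
    idx = indexes.values if isinstance(indexes, IndexSequence) else np.asarray(indexes, dtype=float)
    if X.ndim != 1:
        raise ValueError("X must be a 1D trace")
    if idx.shape != X.shape:
        raise ValueError(f"index length {idx.shape} does not match trace length {X.shape}")
    L = len(X)
    if idx.min() < 0 or idx.max() > L - 1:
        raise ValueError("indexes outside [0, L-1]; clamp them in draw_indexes")
    lo = np.floor(idx).astype(np.intp)
    hi = np.ceil(idx).astype(np.intp)
    frac = idx - lo
    return X[lo] + frac * (X[hi] - X[lo])


def brownian_augment(X, sigma: float, seed=None) -> np.ndarray:
    """Create a virtual trace from ``X`` via a Brownian index walk.

    Composition of :func:`draw_indexes` and :func:`interpolate_trace`;
    ``sigma = 0`` returns ``X`` unchanged (bit-exact).
    """
    X = np.asarray(X, dtype=float)
    indexes = draw_indexes(len(X), sigma, seed)
    return interpolate_trace(X, indexes)


def uniform_stretch(X, factor: float) -> np.ndarray:
    """Globally stretch (factor > 1) or squeeze (factor < 1) a trace.

    Equivalent to interpolating at the deterministic walk ``i0[n] = n /
    factor`` clamped to ``[0, L-1]``; the output keeps length ``L``, samples
    past the end holding the final (padding) value.
    """
    if not factor > 0:
        raise ValueError(f"stretch factor must be > 0, got {factor}")
    X = np.asarray(X, dtype=float)
    L = len(X)
    idx = np.minimum(np.arange(L, dtype=float) / factor, float(L - 1))
    return interpolate_trace(X, idx)


def add_noise(X, noise_std: float, seed=None) -> np.ndarray:
    """Add i.i.d. Gaussian measurement noise to every sample."""
    if noise_std < 0:
        raise ValueError(f"noise_std must be >= 0, got {noise_std}")
    X = np.asarray(X, dtype=float)
    if noise_std == 0:
        return X.copy()
    return X + _as_rng(seed).normal(0.0, noise_std, size=X.shape)


def scale_magnitude(X, factor: float) -> np.ndarray:
    """Multiply the whole trace by a magnitude-jitter factor."""
    return np.asarray(X, dtype=float) * factor


def shift_baseline(X, offset: float) -> np.ndarray:
    """Add a constant baseline offset to the whole trace."""
    return np.asarray(X, dtype=float) + offset


def equivalent_stretch_std(
    sigma: float, event_length: int, n_draws: int = 100_000, seed=None
) -> float:
    """Standard deviation of the uniform stretch equivalent to a Brownian walk.

    Over ``n_draws`` Brownian walks with step std ``sigma``, measures the
    empirical standard deviation of the relative event-length change
    ``i0[event_length-1] / (event_length-1)``.  A global stretch with factors
    drawn ``N(1, returned value)`` then introduces the same event-length
    variation as the Brownian augmentation — the control condition in the
    augmentation comparison.  The closed form is ``sigma / sqrt(event_length
    - 1)``; this routine estimates it by Monte Carlo from actual walk
    endpoints.
    """
    if event_length < 2:
        raise ValueError(f"event_length must be >= 2, got {event_length}")
    if n_draws < 2:
        raise ValueError(f"n_draws must be >= 2, got {n_draws}")
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return 0.0
    rng = _as_rng(seed)
    m = event_length - 1
    ends = np.empty(n_draws, dtype=float)
    chunk = max(1, int(4e6) // m)
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        ends[start:stop] = rng.normal(1.0, sigma, size=(stop - start, m)).sum(axis=1)
    return float(np.std(ends / m, ddof=1))


# ---------------------------------------------------------------------------
# batch augmentation


@dataclass
class AugmentationConfig:
    """Per-epoch augmentation settings.

    ``sigma`` is the Brownian step std (0.9 is the fixed "reasonable"
    comparison value); the classic augmentations mirror the original
    QuipuNet-style training recipe, with defaults exposed here since their
    exact magnitudes live in that training code, not in print.
    """

    sigma: float = 0.9
    stretch_std: float = 0.1
    noise_std: float = 0.05
    magnitude_std: float = 0.08
    baseline_std: float = 0.05
    use_brownian: bool = True
    use_stretch: bool = True
    use_noise: bool = True
    use_magnitude: bool = True
    use_baseline: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma", "stretch_std", "noise_std", "magnitude_std", "baseline_std"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative real, got {v}")

    # -- convenience constructors -----------------------------------------
    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(use_brownian=False, use_stretch=False, use_noise=False,
                   use_magnitude=False, use_baseline=False)

    @classmethod
    def brownian_only(cls, sigma: float = 0.9) -> "AugmentationConfig":
        return cls(sigma=sigma, use_brownian=True, use_stretch=False,
                   use_noise=False, use_magnitude=False, use_baseline=False)

    @classmethod
    def classic(cls, stretch_std: float = 0.1, noise_std: float = 0.05,
                magnitude_std: float = 0.08, baseline_std: float = 0.05) -> "AugmentationConfig":
        """Stretch + noise + magnitude + baseline, no Brownian walk."""
        return cls(stretch_std=stretch_std, noise_std=noise_std,
                   magnitude_std=magnitude_std, baseline_std=baseline_std,
                   use_brownian=False)

    @classmethod
    def stretch_only(cls, stretch_std: float) -> "AugmentationConfig":
        return cls(stretch_std=stretch_std, use_brownian=False, use_stretch=True,
                   use_noise=False, use_magnitude=False, use_baseline=False)

    def with_brownian(self, sigma: float) -> "AugmentationConfig":
        return replace(self, sigma=sigma, use_brownian=True)

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AugmentationConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AugmentationConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def _augment_one(x: np.ndarray, config: AugmentationConfig, rng: Generator) -> np.ndarray:
    """Apply enabled augmentations to one trace: stretch -> Brownian ->
    magnitude -> baseline -> noise (noise last keeps its measurement-noise
    meaning)."""
    if config.use_stretch:
        factor = max(rng.normal(1.0, config.stretch_std), 0.05)
        x = uniform_stretch(x, factor)
    if config.use_brownian:
        x = brownian_augment(x, config.sigma, rng)
    if config.use_magnitude:
        x = scale_magnitude(x, rng.normal(1.0, config.magnitude_std))
    if config.use_baseline:
        x = shift_baseline(x, rng.normal(0.0, config.baseline_std))
    if config.use_noise:
        x = add_noise(x, config.noise_std, rng)
    return x


def augment_batch(traces, config: AugmentationConfig, epoch_seed=None) -> np.ndarray:
    """Augment a batch of equal-length traces, one independent substream each.

    The epoch seed is split into one child stream per trace, so re-running
    with the same ``epoch_seed`` reproduces the batch exactly while different
    epochs see fresh draws.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.ndim != 2:
        raise ValueError("traces must be a 2D (n_traces, L) array of equal-length traces")
    n = traces.shape[0]
    if not any((config.use_brownian, config.use_stretch, config.use_noise,
                config.use_magnitude, config.use_baseline)):
        return traces.copy()
    ss = epoch_seed if isinstance(epoch_seed, SeedSequence) else SeedSequence(epoch_seed)
    children = ss.spawn(n)
    out = np.empty_like(traces)
    for i in range(n):
        out[i] = _augment_one(traces[i], config, default_rng(children[i]))
    return out


# ---------------------------------------------------------------------------
# estimator-style wrappers


class BrownianAugmenter(TransformerMixin, BaseEstimator):
    """Brownian-motion trace augmenter with a scikit-learn transformer API.

    Parameters
    ----------
    sigma : float, default=0.9
        Step standard deviation of the augmenting index walk.
    random_state : int or None
        Seeds the index walks; ``transform`` is deterministic per call for a
        fixed ``random_state`` (each row gets an independent substream).
    """

    def __init__(self, sigma: float = 0.9, random_state=None):
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_traces, L)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_traces, L)")
        cfg = AugmentationConfig.brownian_only(self.sigma)
        return augment_batch(X, cfg, epoch_seed=self.random_state)


class TraceAugmenter(TransformerMixin, BaseEstimator):
    """Full per-epoch augmentation pipeline as a transformer.

    Order per trace: stretch -> Brownian -> magnitude -> baseline -> noise,
    each gated by its ``use_*`` flag; see :class:`AugmentationConfig`.
    """

    def __init__(self, sigma: float = 0.9, stretch_std: float = 0.1,
                 noise_std: float = 0.05, magnitude_std: float = 0.08,
                 baseline_std: float = 0.05, use_brownian: bool = True,
                 use_stretch: bool = True, use_noise: bool = True,
                 use_magnitude: bool = True, use_baseline: bool = True,
                 random_state=None):
        self.sigma = sigma
        self.stretch_std = stretch_std
        self.noise_std = noise_std
        self.magnitude_std = magnitude_std
        self.baseline_std = baseline_std
        self.use_brownian = use_brownian
        self.use_stretch = use_stretch
        self.use_noise = use_noise
        self.use_magnitude = use_magnitude
        self.use_baseline = use_baseline
        self.random_state = random_state

    def _config(self) -> AugmentationConfig:
        return AugmentationConfig(
            sigma=self.sigma, stretch_std=self.stretch_std,
            noise_std=self.noise_std, magnitude_std=self.magnitude_std,
            baseline_std=self.baseline_std, use_brownian=self.use_brownian,
            use_stretch=self.use_stretch, use_noise=self.use_noise,
            use_magnitude=self.use_magnitude, use_baseline=self.use_baseline)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_traces, L)")
        self._config()  # validates parameters
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2D (n_traces, L)")
        return augment_batch(X, self._config(), epoch_seed=self.random_state)
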