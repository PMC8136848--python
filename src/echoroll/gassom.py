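"""Windowing of binaural echoes and the GASSOM subspace coder.

The received echo pair is cut into fine (50-sample) and coarse
(100-sample, decimated by 2) windows with a stride of 5 samples, for
three aural streams: binaural (left and right windows concatenated,
dimension 100), monaural left and monaural right (dimension 50).  Each
window is normalized to unit norm, making reconstruction errors
scale-free.

Each of the six (scale x stream) channels is encoded by its own
Generative Adaptive Subspace Self-Organizing Map (GASSOM): a dictionary
of units, each a two-dimensional orthonormal subspace Phi (analogous to a
cortical complex cell).  A unit's response to window x is the squared
projection length ||Phi^T x||^2 and its reconstruction error is
E = ||x - Phi Phi^T x||^2, so response + error = ||x||^2 (= 1 after
normalization).  Windows are softly assigned to units through a
Gaussian likelihood exp(-E / 2 sigma_n^2) chained by a sticky Markov
prior over consecutive windows (the temporal-smoothness constraint), and
learning pulls each unit's subspace toward the windows assigned to it
and to its grid neighbours, followed by re-orthonormalization.

Per echo, the six 400-dimensional (full profile) response vectors are
average-pooled over windows and concatenated into the feature vector
f(t) of dimension 2400.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STREAMS",
    "GassomConfig",
    "GassomDictionary",
    "EncodingResult",
    "extract_windows",
    "pool_features",
]

#: Canonical stream order used for pooling and feature concatenation.
STREAMS = (
    ("fine", "binaural"),
    ("fine", "left"),
    ("fine", "right"),
    ("coarse", "binaural"),
    ("coarse", "left"),
    ("coarse", "right"),
)

FINE_WINDOW = 50
COARSE_WINDOW = 100
WINDOW_STRIDE = 5
_ZERO_NORM_TOL = 1e-12


def _sticky_forward_py(lik: np.ndarray, stay: float, move: float) -> np.ndarray:
    """Causal forward pass of the sticky-assignment Markov chain.

    prior_t = move + (stay - move) * post_{t-1} sums to 1 whenever the
    previous posterior does, so no renormalization of the prior is
    needed.
    """
    n, u = lik.shape
    post = np.empty_like(lik)
    prior = np.full(u, 1.0 / u)
    sm = stay - move
    for i in range(n):
        w = lik[i] * prior
        w /= w.sum()
        post[i] = w
        prior = move + sm * w
    return post


try:  # the recursion is sequential; JIT it when numba is present
    from numba import njit

    _sticky_forward = njit(cache=True, fastmath=True)(_sticky_forward_py)
except ImportError:  # pragma: no cover
    _sticky_forward = _sticky_forward_py


@dataclass(frozen=True)
class GassomConfig:
    """Hyperparameters of one GASSOM.

    The defaults follow the SOM lineage of the algorithm: a square unit
    grid with a Gaussian neighborhood annealed from ``radius_start`` to
    ``radius_end``, a weight-normalized learning rate annealed from 0.3
    to 0.02, and an annealed assignment-noise scale sigma_n.
    ``total_steps`` sets the
    annealing horizon in update calls.  ``stay_prob`` is the sticky
    Markov prior that implements temporal smoothness of assignments.
    """

    n_units: int = 400
    dim: int = 100
    grid_shape: tuple = (20, 20)
    lr_start: float = 0.3
    lr_end: float = 0.02
    radius_start: float = 3.0
    radius_end: float = 0.5
    sigma_n_start: float = 0.4
    sigma_n_end: float = 0.15
    stay_prob: float = 0.9
    total_steps: int = 3000

    def __post_init__(self):
        if self.grid_shape[0] * self.grid_shape[1] != self.n_units:
            raise ValueError("grid_shape must tile n_units")


@dataclass(frozen=True)
class EncodingResult:
    """Per-window GASSOM outputs.

    responses[i, j] = squared projection of window i on unit j;
    errors[i, j] = ||x_i||^2 - responses[i, j]; posterior is the sticky
    soft assignment; winners the max-posterior unit per window;
    window_errors the posterior-weighted reconstruction error per window
    (the E_{s,e,i} entering the reward).
    """

    responses: np.ndarray
    errors: np.ndarray
    posterior: np.ndarray
    winners: np.ndarray
    norms_sq: np.ndarray

    @property
    def window_errors(self) -> np.ndarray:
        return np.einsum("ij,ij->i", self.posterior, self.errors)

    @property
    def mean_response(self) -> np.ndarray:
        return self.responses.mean(axis=0)


class GassomDictionary:
    """A dictionary of two-dimensional orthonormal subspaces on a unit grid."""

    def __init__(self, config: GassomConfig, seed=0):
        self.config = config
        self.step = 0
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(config.n_units, config.dim, 2))
        self.bases = np.linalg.qr(raw)[0]  # orthonormal columns per unit
        gy, gx = np.unravel_index(np.arange(config.n_units), config.grid_shape)
        self._grid = np.stack([gy, gx], axis=1).astype(float)
        self._seed = seed

    # -- annealing ---------------------------------------------------------
    def _anneal(self, start: float, end: float) -> float:
        frac = min(self.step / max(self.config.total_steps, 1), 1.0)
        return float(start * (end / start) ** frac) if start > 0 else end

    @property
    def learning_rate(self) -> float:
        return self._anneal(self.config.lr_start, self.config.lr_end)

    @property
    def neighborhood_radius(self) -> float:
        return self._anneal(self.config.radius_start, self.config.radius_end)

    @property
    def sigma_n(self) -> float:
        return self._anneal(self.config.sigma_n_start, self.config.sigma_n_end)

    # -- encoding ----------------------------------------------------------
    def encode(self, windows: np.ndarray) -> EncodingResult:
        """Encode a (n_windows, dim) batch of consecutive windows.

        Responses and errors follow the projection identity; the soft
        assignment is a causal forward pass of the sticky Markov chain
        over the window sequence.
        """
        X = np.atleast_2d(np.asarray(windows, dtype=float))
        if X.shape[1] != self.config.dim:
            raise ValueError(
                f"window dimension {X.shape[1]} != dictionary dimension "
                f"{self.config.dim}"
            )
        u, d = self.config.n_units, self.config.dim
        # single GEMM: (n, d) @ (d, u*2) -> projection coefficients
        proj = (X @ self.bases.transpose(1, 0, 2).reshape(d, u * 2)).reshape(
            -1, u, 2
        )
        responses = np.einsum("nuk,nuk->nu", proj, proj)
        norms_sq = np.einsum("nd,nd->n", X, X)
        errors = norms_sq[:, None] - responses
        posterior = self._soft_assign(errors)
        winners = posterior.argmax(axis=1)
        return EncodingResult(responses, errors, posterior, winners, norms_sq)

    def _soft_assign(self, errors: np.ndarray) -> np.ndarray:
        n, u = errors.shape
        s2 = 2.0 * self.sigma_n**2
        loglik = -errors / s2
        lik = np.exp(loglik - loglik.max(axis=1, keepdims=True))
        stay = self.config.stay_prob
        move = (1.0 - stay) / max(u - 1, 1)
        return _sticky_forward(lik, stay, move)

    # -- learning ----------------------------------------------------------
    def update(self, windows: np.ndarray, encoding: EncodingResult | None = None):
        """One learning step on a batch of consecutive windows.

        Each unit's basis is pulled toward the projections of the windows
        assigned to it, weighted by the soft assignment and a Gaussian
        neighborhood around each window's winner on the unit grid, then
        re-orthonormalized (QR).  Advances the annealing step.
        """
        X = np.atleast_2d(np.asarray(windows, dtype=float))
        if encoding is None:
            encoding = self.encode(X)
        eta = self.learning_rate
        if eta > 0:
            radius = self.neighborhood_radius
            d2 = np.square(
                self._grid[encoding.winners][:, None, :] - self._grid[None, :, :]
            ).sum(-1)
            nbhd = np.exp(-d2 / (2.0 * radius**2))
            W = encoding.posterior * nbhd
            u, d = self.config.n_units, self.config.dim
            proj = (X @ self.bases.transpose(1, 0, 2).reshape(d, u * 2)).reshape(
                -1, u, 2
            )
            weighted = (W[:, :, None] * proj).reshape(-1, u * 2)
            delta = (X.T @ weighted).reshape(d, u, 2).transpose(1, 0, 2)
            # normalize each unit's pull by its total assignment weight so
            # the step size is batch-size independent (batch-SOM style)
            delta = delta / (W.sum(axis=0)[:, None, None] + 1e-3)
            if not np.all(np.isfinite(delta)):
                raise FloatingPointError("NaN/inf in GASSOM update")
            self.bases = np.linalg.qr(self.bases + eta * delta)[0]
        self.step += 1
        return self

    # -- serialization -----------------------------------------------------
    def save(self, group) -> None:
        """Write state into an open h5py group."""
        group.create_dataset("bases", data=self.bases)
        group.attrs["step"] = self.step
        group.attrs["seed"] = self._seed
        for k, v in vars(self.config).items():
            group.attrs[f"cfg_{k}"] = v

    @classmethod
    def load(cls, group) -> "GassomDictionary":
        cfg_kwargs = {
            k[4:]: group.attrs[k] for k in group.attrs if k.startswith("cfg_")
        }
        cfg_kwargs["grid_shape"] = tuple(int(x) for x in cfg_kwargs["grid_shape"])
        for key in ("n_units", "dim", "total_steps"):
            cfg_kwargs[key] = int(cfg_kwargs[key])
        seed = group.attrs["seed"]
        if isinstance(seed, np.ndarray):
            seed = [int(s) for s in seed]
        else:
            seed = int(seed)
        obj = cls(GassomConfig(**cfg_kwargs), seed=seed)
        obj.bases = group["bases"][()]
        obj.step = int(group.attrs["step"])
        return obj


def _strided_windows(x: np.ndarray, length: int, stride: int) -> np.ndarray:
    if len(x) < length:
        return np.zeros((0, length))
    view = np.lib.stride_tricks.sliding_window_view(x, length)
    return view[::stride].copy()


def extract_windows(echo) -> dict[tuple, np.ndarray]:
    """Cut a binaural echo into the six normalized window streams.

    Fine windows are 50 raw samples; coarse windows are 100 samples
    decimated by 2 (every other sample), so every stream vector has 50
    samples per ear.  Binaural vectors concatenate [left; right]
    (dimension 100); monaural vectors are single-ear (dimension 50).
    Stride is 5 samples.  Every vector is normalized to unit norm;
    zero-norm windows are dropped (for the binaural stream, a pair is
    dropped when the concatenation has zero norm).

    Returns a dict keyed by :data:`STREAMS`.  Streams are empty (with a
    warning) when the echo is shorter than the coarse window.
    """
    left, right = np.asarray(echo.left, float), np.asarray(echo.right, float)
    if len(left) < COARSE_WINDOW:
        import warnings

        warnings.warn("echo shorter than one coarse window; empty streams")
    out: dict[tuple, np.ndarray] = {}
    for scale, length, decim in (("fine", FINE_WINDOW, 1), ("coarse", COARSE_WINDOW, 2)):
        wl = _strided_windows(left, length, WINDOW_STRIDE)[:, ::decim]
        wr = _strided_windows(right, length, WINDOW_STRIDE)[:, ::decim]
        bin_ = np.concatenate([wl, wr], axis=1)
        for name, W in (("binaural", bin_), ("left", wl), ("right", wr)):
            norms = np.linalg.norm(W, axis=1)
            # absolute guard plus a relative one: numerically-silent
            # stretches (e.g. convolution tails) must not be normalized
            # up into junk windows
            floor = max(_ZERO_NORM_TOL, 1e-6 * norms.max(initial=0.0))
            keep = norms > floor
            out[(scale, name)] = W[keep] / norms[keep, None]
    return out


def pool_features(encodings: dict[tuple, EncodingResult]) -> np.ndarray:
    """Average-pool responses over windows and concatenate the six streams.

    Returns the feature vector f(t); with 400-unit GASSOMs its dimension
    is 2400.
    """
    parts = []
    for stream in STREAMS:
        if stream not in encodings:
            raise ValueError(f"missing stream {stream}")
        enc = encodings[stream]
        if enc.responses.shape[0] == 0:
            raise ValueError(f"empty window stream {stream}")
        parts.append(enc.mean_response)
    return np.concatenate(parts)
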