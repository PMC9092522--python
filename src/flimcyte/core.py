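"""Core domain types shared across the pipeline.

Time-resolved photon data are represented as per-channel TCSPC histogram
cubes with shape ``(T, Y, X)`` (time bins first), with a :class:`TimeAxis`
describing the temporal calibration and an :class:`IRFModel` describing the
instrument response function that blurs every decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeAxis",
    "IRFModel",
    "DecayParams",
    "LifetimeImage",
    "LabelMasks",
]


@dataclass(frozen=True)
class TimeAxis:
    """Temporal calibration of a TCSPC histogram.

    Parameters
    ----------
    n_bins : int
        Number of time bins (>= 16).
    bin_width : float
        Width of one bin in nanoseconds.
    origin : float
        Time of the center of bin 0, in nanoseconds.
    """

    n_bins: int = 512
    bin_width: float = 12.5 / 512
    origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError(f"n_bins must be >= 16, got {self.n_bins}")
        if self.bin_width <= 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")

    @property
    def span(self) -> float:
        """Total time span covered by the histogram (ns)."""
        return self.n_bins * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        """Bin-center times (ns), shape ``(n_bins,)``."""
        return self.origin + np.arange(self.n_bins) * self.bin_width


@dataclass(frozen=True)
class IRFModel:
    """Instrument response function.

    Either an analytic Gaussian of given FWHM centered at ``t0`` (ns after
    the start of the record window), or a tabulated per-bin weight vector
    spanning the full time axis.  Weights are normalized to unit sum before
    convolution, so the IRF redistributes photons in time without creating
    or destroying them.
    """

    shape: str = "gaussian"
    fwhm: float = 0.240
    t0: float = 0.6
    table: np.ndarray | None = None

    _SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "tabulated", "delta"):
            raise ValueError(f"unknown IRF shape {self.shape!r}")
        if self.shape == "gaussian" and self.fwhm <= 0:
            raise ValueError("gaussian IRF requires fwhm > 0")
        if self.shape == "tabulated":
            if self.table is None:
                raise ValueError("tabulated IRF requires a table")
            t = np.asarray(self.table, dtype=float)
            if np.any(t < 0):
                raise ValueError("IRF table weights must be nonnegative")
            if t.sum() <= 0:
                raise ValueError("IRF table must have positive total weight")

    def kernel(self, axis: TimeAxis) -> np.ndarray:
        """Per-bin IRF weights over ``axis``, normalized to unit sum."""
        if self.shape == "delta":
            k = np.zeros(axis.n_bins)
            k[0] = 1.0
            return k
        if self.shape == "tabulated":
            t = np.asarray(self.table, dtype=float)
            if t.size != axis.n_bins:
                raise ValueError(
                    f"tabulated IRF length {t.size} != n_bins {axis.n_bins}"
                )
            return t / t.sum()
        sigma = self.fwhm * self._SIGMA_PER_FWHM
        t = np.arange(axis.n_bins) * axis.bin_width
        k = np.exp(-0.5 * ((t - self.t0) / sigma) ** 2)
        s = k.sum()
        if s <= 0:
            raise ValueError("IRF kernel underflowed to zero on this axis")
        return k / s

    @classmethod
    def delta(cls) -> "IRFModel":
        """An idealized instantaneous IRF (identity under convolution)."""
        return cls(shape="delta")


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the two-component exponential decay model

    ``I(t) = A * [a1 * exp(-t/tau1) + (1 - a1) * exp(-t/tau2)] + C``

    where ``a1`` is the fractional contribution of the short-lifetime
    component; the second fraction is ``1 - a1`` by construction.
    """

    alpha1: float
    tau1: float
    tau2: float
    amplitude: float = 1000.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha1 <= 1.0):
            raise ValueError(f"alpha1 must be in [0, 1], got {self.alpha1}")
        if self.tau1 <= 0:
            raise ValueError(f"tau1 must be > 0, got {self.tau1}")
        if self.tau2 < self.tau1:
            raise ValueError(
                f"require tau1 <= tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def tau_m(self) -> float:
        """Amplitude-weighted mean lifetime (ns)."""
        return self.alpha1 * self.tau1 + self.alpha2 * self.tau2


@dataclass
class LifetimeImage:
    """Per-pixel fitted decay parameters of one spectral channel.

    All maps share shape ``(Y, X)``.  Pixels that were excluded (low
    signal) or failed to converge are marked invalid and carry NaN in
    every parameter map.  ``tau_m`` is definitionally
    ``alpha1 * tau1 + (1 - alpha1) * tau2`` on valid pixels.
    """

    alpha1: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    tau_m: np.ndarray
    background: np.ndarray
    chi2: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray

    MAPS = ("alpha1", "tau1", "tau2", "tau_m", "background", "chi2", "intensity")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LifetimeImage":
        nan = lambda: np.full(shape, np.nan, dtype=np.float32)  # noqa: E731
        return cls(
            alpha1=nan(), tau1=nan(), tau2=nan(), tau_m=nan(),
            background=nan(), chi2=nan(),
            intensity=np.zeros(shape, dtype=np.float64),
            valid=np.zeros(shape, dtype=bool),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.alpha1.shape


@dataclass
class LabelMasks:
    """Nucleus / cell / cytoplasm label images on a common label space.

    Labels are consecutive positive integers starting at 1; background is
    0.  For every label ``k``, nucleus(k) is a subset of cell(k) and
    cytoplasm(k) = cell(k) minus nucleus(k).
    """

    nuclei: np.ndarray
    cells: np.ndarray
    cytoplasm: np.ndarray
    empty_cytoplasm: list = field(default_factory=list)

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the cell image."""
        lab = np.unique(self.cells)
        return lab[lab > 0]

    def validate(self) -> None:
        for k in self.labels():
            nuc = self.nuclei == k
            cell = self.cells == k
            if np.any(nuc & ~cell):
                raise ValueError(f"nucleus {k} extends outside its cell")
            cyto = self.cytoplasm == k
            if np.any(cyto & nuc):
                raise ValueError(f"cytoplasm {k} overlaps its nucleus")
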