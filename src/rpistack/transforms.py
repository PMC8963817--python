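"""Feature-space remapping of the raw molecule vectors.

The default remap is the discrete Hilbert transform: in the frequency
domain, components at strictly positive frequencies are multiplied by -i,
strictly negative frequencies by +i, and the DC (and, for even length, the
Nyquist) bin is zeroed; the result is real and length-preserving.  This is
a pure 90-degree phase shifter — spectral magnitudes away from DC/Nyquist
are untouched, so zero-mean signals keep their energy.  Auto-covariance and
single-level Haar wavelet remaps are provided as baselines, plus identity.

``make_pair_features`` applies the chosen transform to the protein and RNA
raw vectors independently and concatenates protein-first (343 + 352 = 695
under the default configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
import scipy.signal

METHODS = ("hilbert", "autocovariance", "wavelet", "identity")


@dataclass(frozen=True)
class TransformSpec:
    method: str = "hilbert"
    ac_lags: int = 8          # lags per molecule vector for autocovariance
    wavelet_name: str = "haar"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown transform {self.method!r}; choose from {METHODS}")
        if self.ac_lags < 1:
            raise ValueError("ac_lags must be >= 1")


def hilbert(x: np.ndarray) -> np.ndarray:
    """Discrete Hilbert transform (imaginary part of the analytic signal)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("hilbert requires a 1-D vector of length >= 2")
    return np.imag(scipy.signal.hilbert(x))


def inverse_hilbert(xh: np.ndarray) -> np.ndarray:
    """Back-transform: recovers x minus its DC (and Nyquist) component."""
    return -hilbert(xh)


def autocovariance(x: np.ndarray, lags: int = 8) -> np.ndarray:
    """Lagged auto-covariances: entry l-1 = (1/(L-l)) sum_t (x_t - x̄)(x_{t+l} - x̄)."""
    x = np.asarray(x, dtype=np.float64)
    L = x.size
    if lags >= L:
        raise ValueError(f"lags ({lags}) must be smaller than vector length ({L})")
    xc = x - x.mean()
    return np.array([(xc[:L - l] * xc[l:]).sum() / (L - l) for l in range(1, lags + 1)])


def wavelet(x: np.ndarray, name: str = "haar") -> np.ndarray:
    """Single-level DWT: approximation then detail coefficients.

    Odd-length inputs are zero-padded to even length before decomposition,
    so the output length is the (padded) input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("wavelet requires length >= 2")
    if x.size % 2:
        x = np.concatenate([x, [0.0]])
    cA, cD = pywt.dwt(x, name)
    return np.concatenate([cA, cD])


def apply_transform(x: np.ndarray, spec: TransformSpec) -> np.ndarray:
    if spec.method == "identity":
        return np.asarray(x, dtype=np.float64)
    if spec.method == "hilbert":
        return hilbert(x)
    if spec.method == "autocovariance":
        return autocovariance(x, lags=spec.ac_lags)
    return wavelet(x, name=spec.wavelet_name)


@dataclass
class PairFeatureVector:
    rna_id: str
    protein_id: str
    label: int
    values: np.ndarray


def make_pair_features(protein_vec: np.ndarray, rna_vec: np.ndarray,
                       spec: TransformSpec = TransformSpec(),
                       expected_dims=(343, 352)) -> np.ndarray:
    """Transform each molecule's raw vector independently, concat protein-first."""
    protein_vec = np.asarray(protein_vec, dtype=np.float64)
    rna_vec = np.asarray(rna_vec, dtype=np.float64)
    if expected_dims is not None:
        if protein_vec.size != expected_dims[0]:
            raise ValueError(f"protein vector has length {protein_vec.size}, expected {expected_dims[0]}")
        if rna_vec.size != expected_dims[1]:
            raise ValueError(f"RNA vector has length {rna_vec.size}, expected {expected_dims[1]}")
    out = np.concatenate([apply_transform(protein_vec, spec), apply_transform(rna_vec, spec)])
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values in pair feature vector")
    return out
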