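"""Global principal dynamic modes (PDMs) from stacked cohort kernels.

For each input (BP or CO2), the first-order kernel and the
standard-deviation-scaled columns of the second-order self-kernel of every
subject x condition are concatenated into a rectangular matrix Q (rows
indexed by lag).  The left singular vectors of Q associated with the
leading singular values are the cohort-level global PDMs: a common filter
bank whose outputs feed subject-specific static nonlinearities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .laguerre import VolterraKernels
from .spectra import DEFAULT_NFFT, KernelSpectrum, kernel_power_spectrum

__all__ = [
    "KernelStack",
    "GlobalPDMSet",
    "assemble_kernel_matrix",
    "extract_global_pdms",
    "pdm_frequency_profile",
]

INPUT_LABELS = ("BP", "CO2")


@dataclass
class KernelStack:
    """Stacked per-subject kernel blocks for one input.

    Each subject x condition contributes 1 + M columns:
    ``[k1 | sd * k2[:, 0] | ... | sd * k2[:, M-1]]``.  Pre-condition blocks
    come first, then post, subjects in the order given.
    """

    input_label: str
    Q: np.ndarray
    column_index: list  # (subject_id, condition, role) per column

    @property
    def M(self) -> int:
        return self.Q.shape[0]


@dataclass
class GlobalPDMSet:
    """Orthonormal cohort-level impulse responses (columns of ``pdms``)."""

    input_label: str
    pdms: np.ndarray               # (M, H)
    singular_values: np.ndarray    # all singular values, descending
    H: int

    @property
    def M(self) -> int:
        return self.pdms.shape[0]


def assemble_kernel_matrix(kernel_sets, input_label: str) -> KernelStack:
    """Build the stacked kernel matrix Q for one input.

    Parameters
    ----------
    kernel_sets : list of (subject_id, condition, VolterraKernels, input_sd)
        ``input_sd`` is the standard deviation of that subject's
        preprocessed input series; it scales the second-order columns so
        first- and second-order contributions are commensurate.
    input_label : {"BP", "CO2"}
    """
    if input_label not in INPUT_LABELS:
        raise ValueError(f"input_label must be one of {INPUT_LABELS}")
    if not kernel_sets:
        raise ValueError("kernel_sets is empty")
    Ms = {ks[2].M for ks in kernel_sets}
    if len(Ms) != 1:
        raise ValueError(f"kernels disagree on memory M: {sorted(Ms)}")
    M = Ms.pop()

    blocks, index = [], []
    ordered = ([ks for ks in kernel_sets if ks[1] == "pre"]
               + [ks for ks in kernel_sets if ks[1] != "pre"])
    for subject_id, condition, kernels, sd in ordered:
        if not sd > 0:
            raise ValueError(f"input_sd must be positive (subject {subject_id})")
        if input_label == "BP":
            k1, k2 = kernels.kP, kernels.kPP
        else:
            k1, k2 = kernels.kC, kernels.kCC
        blocks.append(np.column_stack([k1, sd * k2]))
        index.append((subject_id, condition, "first_order"))
        index.extend((subject_id, condition, f"second_order_col{m}")
                     for m in range(M))
    return KernelStack(input_label=input_label, Q=np.hstack(blocks),
                       column_index=index)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude element positive."""
    U = U.copy()
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
    return U


def extract_global_pdms(stack: KernelStack, H: int) -> GlobalPDMSet:
    """SVD of the kernel stack; first H left singular vectors are the PDMs.

    Requesting H beyond the numerical rank raises a warning (the extra
    vectors are arbitrary directions in the null space) but still returns
    H columns.
    """
    M = stack.M
    if not 1 <= H <= M:
        raise ValueError(f"need 1 <= H <= M={M}")
    U, s, Vt = np.linalg.svd(stack.Q, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(stack.Q.shape) * np.finfo(float).eps))
    if H > rank:
        warnings.warn(
            f"H={H} exceeds numerical rank {rank}; trailing PDMs are "
            "null-space directions", UserWarning, stacklevel=2)
    return GlobalPDMSet(input_label=stack.input_label,
                        pdms=_fix_signs(U[:, :H]),
                        singular_values=s, H=H)


def pdm_frequency_profile(pdm, fs: float = 1.0, nfft: int = DEFAULT_NFFT):
    """Magnitude spectrum of a PDM and the frequency of its peak above DC.

    Returns ``(KernelSpectrum, peak_frequency)`` where the spectrum's
    ``power`` field holds the magnitude (not squared) for plotting parity
    with time-domain mode shapes.
    """
    ps = kernel_power_spectrum(pdm, fs=fs, nfft=nfft)
    mag = np.sqrt(ps.power)
    spec = KernelSpectrum(freqs=ps.freqs, power=mag, nfft=nfft, fs=fs)
    peak = float(ps.freqs[1:][np.argmax(mag[1:])])
    return spec, peak
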