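"""Shared test utilities: finite-difference gradient checking."""

from __future__ import annotations

import numpy as np

from ecatbrats.nn import Parameter


def gradcheck(fn, *arrays, eps: float = 1e-6, tol: float = 1e-4) -> None:
    """Compare reverse-mode gradients of ``fn(*tensors).sum()`` against
    central finite differences, elementwise, in float64."""
    tensors = [Parameter(np.asarray(a, dtype=np.float64)) for a in arrays]
    out = fn(*tensors)
    (out.sum() if out.data.size > 1 else out).backward()
    for t in tensors:
        numeric = np.zeros_like(t.data)
        flat = t.data.ravel()
        num_flat = numeric.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            f_plus = fn(*tensors).data.sum()
            flat[i] = orig - eps
            f_minus = fn(*tensors).data.sum()
            flat[i] = orig
            num_flat[i] = (f_plus - f_minus) / (2 * eps)
        err = np.abs(numeric - t.grad).max()
        assert err < tol, f"gradient mismatch {err:.2e} for input of shape {t.shape}"
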