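"""Synthetic HOMA2-IR surrogate backend.

The real HOMA2 value comes from the Oxford calculator program, which cannot be
embedded here. This backend is a SYNTHETIC stand-in: a smooth power-law
surface

    HOMA2-IR ~= c * secretagogue^a * glucose^b

whose coefficients were calibrated so that cohort-scale median outputs track
published biobank median values of HOMA2-IR computed with the real calculator
(separately for the insulin and C-peptide inputs). It reproduces the
qualitative behaviour that matters to this pipeline -- strict monotonicity in
the secretagogue at fixed glucose, sublinear growth in glucose, and
HOMA2-IR < HOMA-IR at typical fasting values -- but its individual-level
outputs are NOT the Oxford model's and must not be used clinically.

For quantitative HOMA2 work, dump the reference calculator over a grid and use
:class:`irindices.homa2.GridHOMA2Backend` instead.
"""

from __future__ import annotations

import numpy as np

from .homa2 import _BackendBase

__all__ = ["SyntheticHOMA2Backend"]

# power-law coefficients (c, a, b) per secretagogue kind, calibrated on
# published group-median anchors (normoglycemic / prediabetes / diabetes)
_COEFFS = {
    # HOMA2-IR(insulin): secretagogue in uU/mL (pmol/L / 6.0)
    "insulin": (0.0763, 0.9686, 0.2824),
    # HOMA2-IR(C-peptide): secretagogue in nmol/L
    "cpeptide": (0.9656, 0.9018, 0.4832),
}
_INSULIN_PMOL_PER_UU = 6.0


class SyntheticHOMA2Backend(_BackendBase):
    """Default backend: synthetic power-law surrogate for HOMA2-IR."""

    name = "synthetic-powerlaw"
    version = "1.0"

    def homa2_ir(self, glucose_mmol_l, secretagogue, kind: str):
        """HOMA2-IR surrogate value.

        ``secretagogue`` is insulin in pmol/L (kind='insulin') or C-peptide
        in nmol/L (kind='cpeptide'); glucose in mmol/L. Inputs must lie in
        the declared validity domain.
        """
        self.check_domain(glucose_mmol_l, secretagogue, kind)
        c, a, b = _COEFFS[kind]
        g = np.asarray(glucose_mmol_l, dtype=float)
        s = np.asarray(secretagogue, dtype=float)
        if kind == "insulin":
            s = s / _INSULIN_PMOL_PER_UU
        out = c * s**a * g**b
        return float(out) if out.ndim == 0 else out
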