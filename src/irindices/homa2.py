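"""Pluggable HOMA2-IR backends.

HOMA2-IR comes from the Oxford homeostasis-model computer program, whose
internal physiological equations are not published in closed form. This module
therefore defines a backend *contract* rather than the model itself:

- deterministic;
- monotonically increasing in the secretagogue (insulin or C-peptide) at
  fixed glucose;
- a declared validity domain, outside which a :class:`DomainError` is raised
  (scalar API) or the value is reported missing (battery API).

Two backends ship with the package: :class:`GridHOMA2Backend`, which
interpolates a user-supplied grid of reference-calculator outputs (the
recommended route when calculator access is available), and the synthetic
surrogate in :mod:`irindices.homa2_synthetic`, used as the default so the
pipeline runs without external lookups.
"""

from __future__ import annotations

import json
from typing import Protocol

import numpy as np

from .exceptions import ConfigurationError, DomainError

__all__ = ["HOMA2Backend", "DOMAIN_BOUNDS", "GridHOMA2Backend"]

#: validity domain per input, matching the reference calculator's accepted
#: ranges: glucose mmol/L, insulin pmol/L, C-peptide nmol/L.
DOMAIN_BOUNDS = {
    "glucose": (3.0, 25.0),
    "insulin": (20.0, 400.0),
    "cpeptide": (0.2, 3.5),
}


class HOMA2Backend(Protocol):
    """Contract every HOMA2 backend satisfies."""

    name: str
    version: str

    def homa2_ir(self, glucose_mmol_l, secretagogue, kind: str): ...

    def domain_mask(self, glucose, secretagogue, kind: str): ...


class _BackendBase:
    """Shared domain handling for concrete backends."""

    name = "abstract"
    version = "0"

    def _bounds(self, kind: str):
        if kind not in ("insulin", "cpeptide"):
            raise ConfigurationError(
                f"secretagogue kind must be 'insulin' or 'cpeptide', got {kind!r}"
            )
        return DOMAIN_BOUNDS["glucose"], DOMAIN_BOUNDS[kind]

    def domain_mask(self, glucose, secretagogue, kind: str):
        """Vectorised domain check.

        Returns ``(mask, reasons)``: a boolean array marking in-domain rows
        and a string array with a ``homa2_domain:<field>`` code for rows that
        violate a bound (empty string elsewhere). NaNs are out of domain.
        """
        (glo, ghi), (slo, shi) = self._bounds(kind)
        g = np.asarray(glucose, dtype=float)
        s = np.asarray(secretagogue, dtype=float)
        g_ok = (g >= glo) & (g <= ghi)
        s_ok = (s >= slo) & (s <= shi)
        reasons = np.full(np.broadcast(g, s).shape, "", dtype=object)
        reasons[~s_ok] = f"homa2_domain:{kind}"
        reasons[~g_ok] = "homa2_domain:glucose"
        return g_ok & s_ok, reasons

    def check_domain(self, glucose, secretagogue, kind: str) -> None:
        """Scalar-style strict check: raise DomainError naming the bound."""
        (glo, ghi), (slo, shi) = self._bounds(kind)
        g = np.asarray(glucose, dtype=float)
        s = np.asarray(secretagogue, dtype=float)
        if np.any(~((g >= glo) & (g <= ghi))):
            bad = g[~((g >= glo) & (g <= ghi))].flat[0]
            raise DomainError("glucose_mmol_l", float(bad), glo, ghi)
        if np.any(~((s >= slo) & (s <= shi))):
            bad = s[~((s >= slo) & (s <= shi))].flat[0]
            raise DomainError(kind, float(bad), slo, shi)


class GridHOMA2Backend(_BackendBase):
    """Bilinear interpolation over a grid of reference-calculator outputs.

    Interpolation is bilinear in log-input / log-output space (the model
    surface is close to log-linear there, and outputs are strictly
    positive). Queries outside the grid raise :class:`DomainError` rather
    than extrapolating.

    Parameters
    ----------
    grids : dict
        ``{"insulin": (glucose_axis, secretagogue_axis, values2d),
        "cpeptide": (...)}`` with strictly increasing axes and
        ``values2d[i, j]`` = HOMA2-IR at ``glucose_axis[i]``,
        ``secretagogue_axis[j]``.
    version : str
        Provenance stamp of the calculator run that produced the grid.
    """

    name = "grid"

    def __init__(self, grids: dict, version: str = "unversioned") -> None:
        self.version = version
        self._grids = {}
        for kind, (gax, sax, vals) in grids.items():
            gax = np.asarray(gax, dtype=float)
            sax = np.asarray(sax, dtype=float)
            vals = np.asarray(vals, dtype=float)
            if np.any(np.diff(gax) <= 0) or np.any(np.diff(sax) <= 0):
                raise ConfigurationError("grid axes must be strictly increasing")
            if vals.shape != (gax.size, sax.size):
                raise ConfigurationError("grid value shape mismatch")
            if np.any(vals <= 0):
                raise ConfigurationError("grid values must be strictly positive")
            self._grids[kind] = (gax, sax, np.log(vals))

    @classmethod
    def from_json(cls, path) -> "GridHOMA2Backend":
        with open(path) as fh:
            doc = json.load(fh)
        grids = {
            kind: (g["glucose_mmol_l"], g["secretagogue"], g["homa2_ir"])
            for kind, g in doc["grids"].items()
        }
        return cls(grids, version=doc.get("version", "unversioned"))

    def _bounds(self, kind: str):
        if kind not in self._grids:
            raise ConfigurationError(f"no grid configured for kind {kind!r}")
        gax, sax, _ = self._grids[kind]
        return (gax[0], gax[-1]), (sax[0], sax[-1])

    def homa2_ir(self, glucose_mmol_l, secretagogue, kind: str):
        self.check_domain(glucose_mmol_l, secretagogue, kind)
        gax, sax, vals = self._grids[kind]
        g = np.log(np.asarray(glucose_mmol_l, dtype=float))
        s = np.log(np.asarray(secretagogue, dtype=float))
        lg, ls = np.log(gax), np.log(sax)
        gi = np.clip(np.searchsorted(lg, g, side="right") - 1, 0, lg.size - 2)
        si = np.clip(np.searchsorted(ls, s, side="right") - 1, 0, ls.size - 2)
        tg = (g - lg[gi]) / (lg[gi + 1] - lg[gi])
        ts = (s - ls[si]) / (ls[si + 1] - ls[si])
        v00 = vals[gi, si]
        v01 = vals[gi, si + 1]
        v10 = vals[gi + 1, si]
        v11 = vals[gi + 1, si + 1]
        out = np.exp(
            v00 * (1 - tg) * (1 - ts)
            + v01 * (1 - tg) * ts
            + v10 * tg * (1 - ts)
            + v11 * tg * ts
        )
        return float(out) if out.ndim == 0 else out
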