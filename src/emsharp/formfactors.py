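"""Electron scattering form factors.

The table ships the 5-Gaussian parameterization of Peng et al. (1996) for
neutral atoms, stored as ``f(q) = sum_i a_i exp(-b_i q^2)`` with
``q = sin(theta)/lambda``. All public code in this package works in the
frequency variable ``s = 1/d = 2q`` (1/Å), in which the same factor reads

    f(s) = sum_i a_i exp(-b_i s^2 / 4)

so the Gaussian widths combine additively with atomic B factors:
``f(s) exp(-B s^2/4) = sum_i a_i exp(-(b_i + B) s^2/4)``. Doing the q->s
conversion once at load time keeps factor-of-two mistakes out of the rest
of the code base.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

__all__ = ["FormFactorTable", "default_table"]

_DATA_FILE = "electron_form_factors_peng1996.tsv"


class FormFactorTable:
    """Per-element Gaussian electron scattering factors f(s), s = 1/d."""

    def __init__(self, coefficients: dict[str, tuple[np.ndarray, np.ndarray]]):
        # coefficients[element] = (a, b) with b already in the s-convention,
        # i.e. f(s) = sum a_i exp(-b_i s^2 / 4)
        self._coeff = {
            el.capitalize(): (np.asarray(a, float), np.asarray(b, float))
            for el, (a, b) in coefficients.items()
        }

    @classmethod
    def from_tsv(cls, path_or_text) -> "FormFactorTable":
        """Load a table whose b_i are in the sin(theta)/lambda convention."""
        if hasattr(path_or_text, "read"):
            lines = path_or_text.read().splitlines()
        else:
            with open(path_or_text) as fh:
                lines = fh.read().splitlines()
        coeff = {}
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("element"):
                continue
            parts = line.split()
            el = parts[0]
            vals = np.array(parts[1:], dtype=float)
            a, b = vals[0::2], vals[1::2]
            # stored as f(q)=sum a exp(-b q^2), q = s/2  ->  exponent -b s^2/4:
            # the b_i are used unchanged because evaluate() divides s^2 by 4.
            coeff[el] = (a, b)
        return cls(coeff)

    @property
    def elements(self) -> list[str]:
        return sorted(self._coeff)

    def __contains__(self, element: str) -> bool:
        return element.capitalize() in self._coeff

    def evaluate(self, element: str, s) -> np.ndarray:
        """f(s) in scattering units for frequency s = 1/d (1/Å)."""
        try:
            a, b = self._coeff[element.capitalize()]
        except KeyError:
            raise KeyError(
                f"element {element!r} is not in the form-factor table "
                f"(available: {', '.join(self.elements)})"
            ) from None
        s = np.asarray(s, dtype=float)
        return np.sum(a * np.exp(-b * (s[..., None] ** 2) / 4.0), axis=-1)

    def coefficients(self, element: str) -> tuple[np.ndarray, np.ndarray]:
        a, b = self._coeff[element.capitalize()]
        return a.copy(), b.copy()


def default_table() -> FormFactorTable:
    """The table shipped with the package (H, C, N, O, S, P)."""
    ref = resources.files("emsharp").joinpath("data").joinpath(_DATA_FILE)
    with ref.open() as fh:
        return FormFactorTable.from_tsv(fh)
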