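"""Spectral bases and linear unmixing of multi-color SRS measurements.

A pixel of a multi-color stimulated Raman scattering (SRS) image is a short
vector ``d`` of intensities, one per acquisition wavenumber ("color").  Under
the linear mixing model each pixel is a superposition of the responses of the
chemical constituents present in the focal volume,

    d = S @ c,

where column ``i`` of ``S`` is the spectral response of constituent ``i``
sampled at the acquisition wavenumbers and ``c`` holds the per-constituent
concentrations.  Unmixing solves for ``c`` by applying the Moore–Penrose
pseudo-inverse of ``S``; when the system is square and invertible this is the
exact inverse, otherwise it is the minimum-norm least-squares solution.

Negative coefficients are retained: the pseudo-inverse is linear, and noise on
a pixel near zero concentration legitimately produces small negative values.
Clipping, where wanted, happens downstream at feature-extraction or display
time (see :func:`ramansort.pipeline.extract_features`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Acquisition wavenumbers (cm^-1) used for the two-polymer demonstration:
#: C-H stretch region peaks that separate polystyrene-like and PMMA-like
#: spectra with four colors.
DEFAULT_WAVENUMBERS: tuple[float, ...] = (2899.0, 2954.0, 3006.0, 3034.0)

#: Relative singular-value threshold below which a basis is declared
#: rank-deficient.
RANK_RTOL = 1e-10

WAVENUMBER_COLUMN = "wavenumber_cm-1"


@dataclass(frozen=True)
class SpectralBasis:
    """Per-constituent spectral responses at the acquisition wavenumbers.

    Parameters
    ----------
    constituent_names
        One label per constituent (column of ``responses``).
    wavenumbers
        Acquisition wavenumbers in cm^-1, one per color (row of
        ``responses``).  Must be distinct.
    responses
        ``(n_colors, n_constituents)`` response matrix in arbitrary signal
        units.  Must have full column rank and at least as many colors as
        constituents.
    """

    constituent_names: tuple[str, ...]
    wavenumbers: np.ndarray
    responses: np.ndarray
    _pinv: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        resp = np.atleast_2d(np.asarray(self.responses, dtype=float))
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "constituent_names", tuple(self.constituent_names))
        if not np.all(np.isfinite(resp)):
            raise ValueError("response matrix contains non-finite values")
        if wn.ndim != 1 or resp.shape[0] != wn.size:
            raise ValueError(
                f"responses has {resp.shape[0]} rows but {wn.size} wavenumbers given"
            )
        if len(self.constituent_names) != resp.shape[1]:
            raise ValueError("one constituent name per response column required")
        if np.unique(wn).size != wn.size:
            raise ValueError("acquisition wavenumbers must be distinct")
        if self.n_colors < self.n_constituents:
            raise ValueError(
                f"{self.n_colors} colors cannot resolve {self.n_constituents} constituents"
            )
        s = np.linalg.svd(resp, compute_uv=False)
        if s[-1] <= RANK_RTOL * s[0]:
            raise ValueError(
                "response matrix is rank deficient "
                f"(singular values {s}); constituents are not spectrally separable"
            )
        object.__setattr__(self, "_pinv", np.linalg.pinv(resp))

    @property
    def n_colors(self) -> int:
        return self.responses.shape[0]

    @property
    def n_constituents(self) -> int:
        return self.responses.shape[1]

    @property
    def condition_number(self) -> float:
        """2-norm condition number of the response matrix."""
        s = np.linalg.svd(self.responses, compute_uv=False)
        return float(s[0] / s[-1])

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "constituent_names": list(self.constituent_names),
            "wavenumbers": self.wavenumbers.tolist(),
            "responses": self.responses.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpectralBasis":
        payload = json.loads(Path(path).read_text())
        return cls(
            constituent_names=tuple(payload["constituent_names"]),
            wavenumbers=np.asarray(payload["wavenumbers"], dtype=float),
            responses=np.asarray(payload["responses"], dtype=float),
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.responses, columns=list(self.constituent_names))
        df.insert(0, WAVENUMBER_COLUMN, self.wavenumbers)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralBasis":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c != WAVENUMBER_COLUMN]
        return cls(
            constituent_names=tuple(names),
            wavenumbers=df[WAVENUMBER_COLUMN].to_numpy(dtype=float),
            responses=df[names].to_numpy(dtype=float),
        )


def load_spectra_table(path: str | Path) -> pd.DataFrame:
    """Read a per-constituent spectra table (CSV with a wavenumber column)."""
    df = pd.read_csv(path)
    if WAVENUMBER_COLUMN not in df.columns:
        raise ValueError(f"spectra table must contain a {WAVENUMBER_COLUMN!r} column")
    return df


def build_basis(
    spectra_table: pd.DataFrame,
    selected_wavenumbers: Sequence[float],
) -> SpectralBasis:
    """Sample per-constituent spectra at the acquisition wavenumbers.

    ``spectra_table`` holds each constituent's spectrum tabulated over
    wavenumber (column ``wavenumber_cm-1`` plus one column per constituent).
    Values between tabulated points are obtained by linear interpolation.

    Raises
    ------
    ValueError
        If a selected wavenumber falls outside the tabulated range, if fewer
        wavenumbers than constituents are selected, or if the sampled matrix
        is rank deficient.
    """
    sel = np.asarray(selected_wavenumbers, dtype=float)
    wn = spectra_table[WAVENUMBER_COLUMN].to_numpy(dtype=float)
    order = np.argsort(wn)
    wn = wn[order]
    names = [c for c in spectra_table.columns if c != WAVENUMBER_COLUMN]
    if sel.size < len(names):
        raise ValueError(
            f"{sel.size} wavenumbers cannot resolve {len(names)} constituents"
        )
    if np.any(sel < wn[0]) or np.any(sel > wn[-1]):
        raise ValueError(
            f"selected wavenumbers must lie within the tabulated range "
            f"[{wn[0]}, {wn[-1]}] cm^-1"
        )
    cols = []
    for name in names:
        spectrum = spectra_table[name].to_numpy(dtype=float)[order]
        cols.append(np.interp(sel, wn, spectrum))
    responses = np.stack(cols, axis=1)
    return SpectralBasis(tuple(names), sel, responses)


def unmix(d: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Per-pixel linear decomposition: minimum-norm least-squares ``c``.

    For a square invertible basis this equals the exact inverse solution.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (basis.n_colors,):
        raise ValueError(
            f"pixel vector has shape {d.shape}, expected ({basis.n_colors},)"
        )
    if not np.all(np.isfinite(d)):
        raise ValueError("pixel vector contains non-finite values")
    return basis._pinv @ d


def unmix_image(image: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Apply :func:`unmix` to every pixel of a ``(lines, lateral, colors)`` stack.

    Returns a ``(lines, lateral, n_constituents)`` array on the same spatial
    grid.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[-1] != basis.n_colors:
        raise ValueError(
            f"image shape {image.shape} incompatible with a {basis.n_colors}-color basis"
        )
    return np.einsum("ij,xyj->xyi", basis._pinv, image)


def toy_polymer_spectra(
    wavenumber_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Synthetic two-polymer spectra over the C-H stretch window.

    Generates smooth Gaussian-peak curves emulating the qualitative shapes of
    polystyrene (aliphatic ~2900 plus aromatic ~3030 cm^-1 C-H stretches) and
    poly(methyl methacrylate) (ester-methyl ~2950 cm^-1), so the default
    four-color sampling yields a well-conditioned 4x2 basis.  These are
    synthetic stand-ins, not measured spectra.
    """
    if wavenumber_grid is None:
        wavenumber_grid = np.arange(2800.0, 3101.0, 1.0)
    wn = np.asarray(wavenumber_grid, dtype=float)

    def peak(center: float, width: float, amp: float) -> np.ndarray:
        return amp * np.exp(-0.5 * ((wn - center) / width) ** 2)

    ps = peak(2899.0, 18.0, 0.85) + peak(3034.0, 14.0, 1.0) + peak(3006.0, 12.0, 0.45)
    pmma = peak(2954.0, 20.0, 1.0) + peak(2899.0, 25.0, 0.30) + peak(3006.0, 30.0, 0.12)
    return pd.DataFrame({WAVENUMBER_COLUMN: wn, "PS": ps, "PMMA": pmma})


def default_polymer_basis() -> SpectralBasis:
    """Four-color PS/PMMA-like basis at the default acquisition wavenumbers."""
    return build_basis(toy_polymer_spectra(), DEFAULT_WAVENUMBERS)
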