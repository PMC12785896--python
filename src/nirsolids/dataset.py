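"""Spectra container and CSV I/O.

The universal data currency is :class:`SpectraSet`: a samples x wavelengths
absorbance matrix on a strictly increasing nanometre grid, with optional
per-sample reference values (soluble solids content, %).

CSV dialect
-----------
One self-describing comma-separated UTF-8 file::

    sample_id,900.0,901.0,...,1800.0[,reference]
    s001,0.812,0.815,...,1.021[,6.4]

The header row carries the wavelength grid in nm; the first column holds
sample identifiers; an optional final column named ``reference`` holds the
reference values. A separate two-column ``sample_id,reference`` file is also
accepted by :func:`read_reference_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_csv",
    "average_replicates",
]


class SpectraFormatError(ValueError):
    """Raised for malformed spectra files or inconsistent containers."""


@dataclass
class SpectraSet:
    """Absorbance spectra with an optional reference vector.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per spectrum row.
    wavelengths : ndarray, shape (p,)
        Strictly increasing grid in nm.
    absorbance : ndarray, shape (n, p)
        Absorbance in AU; must be finite.
    reference : ndarray, shape (n,), optional
        Reference values (SSC, %), one per sample.
    metadata : dict
        Free-form provenance (e.g. generator seed, injected outlier rows).
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    absorbance: np.ndarray
    reference: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise SpectraFormatError(
                f"{len(self.sample_ids)} sample ids for {n} spectra rows"
            )
        if self.wavelengths.shape != (p,):
            raise SpectraFormatError(
                f"{self.wavelengths.size} wavelengths for {p} absorbance columns"
            )
        if p > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraFormatError("non-finite absorbance values")
        if self.reference is not None:
            if self.reference.shape != (n,):
                raise SpectraFormatError(
                    f"reference length {self.reference.size} != n_samples {n}"
                )
            if not np.all(np.isfinite(self.reference)):
                raise SpectraFormatError("non-finite reference values")

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def take(self, indices) -> "SpectraSet":
        """Row subset (new object, shared metadata copy)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            reference=None if self.reference is None else self.reference[idx],
            metadata=dict(self.metadata),
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectraSet":
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))


def read_spectra_csv(path) -> SpectraSet:
    """Read a spectra CSV (dialect in the module docstring).

    Raises
    ------
    SpectraFormatError
        On ragged rows, non-numeric cells, or a non-increasing grid; the
        message names the offending row/column where pandas reports it.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"{path}: malformed CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "sample_id":
        raise SpectraFormatError(f"{path}: first header cell must be 'sample_id'")
    has_ref = df.columns[-1] == "reference"
    wl_cols = df.columns[1 : -1 if has_ref else df.shape[1]]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavelength header ({exc})") from exc
    if wavelengths.size > 1 and not np.all(np.diff(wavelengths) > 0):
        raise SpectraFormatError(f"{path}: wavelength grid not strictly increasing")
    body = df[wl_cols]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise SpectraFormatError(
            f"{path}: non-numeric or missing cell at data row {r}, column {wl_cols[c]!r}"
        )
    reference = None
    if has_ref:
        try:
            reference = df["reference"].astype(float).to_numpy()
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: non-numeric reference value ({exc})") from exc
    return SpectraSet(
        sample_ids=df["sample_id"].tolist(),
        wavelengths=wavelengths,
        absorbance=numeric.to_numpy(dtype=float),
        reference=reference,
    )


def write_spectra_csv(data: SpectraSet, path) -> Path:
    """Write `data` in the CSV dialect; lossless to >=12 significant digits."""
    path = Path(path)
    cols = {"sample_id": data.sample_ids}
    for j, wl in enumerate(data.wavelengths):
        cols[format(wl, ".12g")] = data.absorbance[:, j]
    if data.reference is not None:
        cols["reference"] = data.reference
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def read_reference_csv(path) -> tuple[list[str], np.ndarray]:
    """Read a two-column ``sample_id,reference`` companion file."""
    df = pd.read_csv(path, header=0, dtype={0: str})
    if list(df.columns) != ["sample_id", "reference"]:
        raise SpectraFormatError(f"{path}: expected header 'sample_id,reference'")
    return df["sample_id"].tolist(), df["reference"].astype(float).to_numpy()


def average_replicates(data: SpectraSet, group_labels) -> SpectraSet:
    """Average replicate scans per sample.

    One output row per distinct label, in first-appearance order; absorbance
    (and reference, if present) are arithmetic means over each group.
    """
    labels = [str(g) for g in group_labels]
    if len(labels) != data.n_samples:
        raise SpectraFormatError(
            f"{len(labels)} group labels for {data.n_samples} rows"
        )
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(labels):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(i)
    absorbance = np.vstack([data.absorbance[groups[g]].mean(axis=0) for g in order])
    reference = None
    if data.reference is not None:
        reference = np.array([data.reference[groups[g]].mean() for g in order])
    return SpectraSet(
        sample_ids=order,
        wavelengths=data.wavelengths,
        absorbance=absorbance,
        reference=reference,
        metadata=dict(data.metadata),
    )
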