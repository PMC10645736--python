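"""Readers and writers for spectral and tabular artifacts.

Formats:

* wide CSV — first column ``wavenumber``, one column per spectrum, with an
  optional sidecar CSV carrying labels and metadata;
* two-column text — ``wavenumber intensity`` per line for one spectrum;
* JCAMP-DX — single spectra in the ``(X++(Y..Y))`` affine form.

Floats are written with 17 significant digits so writer/reader pairs
round-trip bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .features import FeatureMatrix, SplitIndices
from .simulate import LabeledSpectrumSet, Spectrum

__all__ = [
    "read_spectra",
    "write_wide_csv", "read_wide_csv",
    "write_two_column", "read_two_column",
    "write_jcamp", "read_jcamp",
    "write_feature_matrix", "write_split", "write_json",
]

log = logging.getLogger("sersmix")

_FLOAT_FMT = "%.17g"


def _format_float(x: float) -> str:
    return _FLOAT_FMT % x


def read_spectra(path: str | Path, format: str = "wide-csv",
                 labels_path: str | Path | None = None) -> LabeledSpectrumSet:
    """Read spectra in one of the supported dialects.

    ``format`` is ``wide-csv``, ``two-column-text`` or ``jcamp-dx`` (the
    latter two yield a single-spectrum set).
    """
    if format == "wide-csv":
        return read_wide_csv(path, labels_path)
    if format == "two-column-text":
        return LabeledSpectrumSet([read_two_column(path)])
    if format == "jcamp-dx":
        return LabeledSpectrumSet([read_jcamp(path)])
    raise ValueError(f"unknown spectra format {format!r}")


# -- wide CSV ----------------------------------------------------------------

def write_wide_csv(spectra: LabeledSpectrumSet, path: str | Path,
                   labels_path: str | Path | None = None):
    """Write a set as a wide CSV; optionally a sidecar labels/metadata CSV."""
    path = Path(path)
    data = {"wavenumber": spectra.wavenumbers}
    for i, s in enumerate(spectra):
        data[f"s{i}"] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)
    if labels_path is not None:
        rows = []
        for i, s in enumerate(spectra):
            rows.append({
                "spectrum": f"s{i}",
                "label": s.label if s.label is not None else "",
                "metadata": json.dumps(s.metadata, sort_keys=True),
            })
        pd.DataFrame(rows).to_csv(labels_path, index=False)


def read_wide_csv(path: str | Path,
                  labels_path: str | Path | None = None) -> LabeledSpectrumSet:
    """Read a wide CSV (labels attached from the sidecar when present)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as e:
        raise ParseError(f"cannot parse {path}: {e}") from e
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a wavenumber column plus spectra")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].apply(lambda v: not _is_number(v))
            row = int(np.flatnonzero(bad.values)[0]) if bad.any() else 0
            raise ParseError(f"{path}: non-numeric cell in column {col!r}",
                             line=row + 2)  # header + 1-based
    grid = df.iloc[:, 0].to_numpy(float)
    if np.unique(grid).size != grid.size:
        raise ParseError(f"{path}: duplicated wavenumbers")
    order = np.argsort(grid)
    if not np.array_equal(order, np.arange(grid.size)):
        log.info("re-sorting %s to ascending wavenumbers", path)
    labels, metas = {}, {}
    if labels_path is not None:
        side = pd.read_csv(labels_path)
        for _, row in side.iterrows():
            if not pd.isna(row.get("label", np.nan)) and str(row["label"]) != "":
                labels[row["spectrum"]] = int(row["label"])
            if "metadata" in side.columns and isinstance(row["metadata"], str):
                metas[row["spectrum"]] = json.loads(row["metadata"])
    spectra = []
    for col in df.columns[1:]:
        spectra.append(Spectrum(grid[order], df[col].to_numpy(float)[order],
                                label=labels.get(col), metadata=metas.get(col, {})))
    return LabeledSpectrumSet(spectra)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# -- two-column text ---------------------------------------------------------

def write_two_column(spectrum: Spectrum, path: str | Path):
    path = Path(path)
    with path.open("w") as fh:
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{_format_float(x)} {_format_float(y)}\n")


def read_two_column(path: str | Path) -> Spectrum:
    """Read one ``wavenumber intensity`` pair per line; re-sorts descending
    grids to ascending."""
    path = Path(path)
    xs, ys = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(f"{path}: expected two columns", line=lineno)
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"{path}: non-numeric value {parts!r}", line=lineno)
    if not xs:
        raise ParseError(f"{path}: no data lines")
    x = np.array(xs)
    y = np.array(ys)
    if np.unique(x).size != x.size:
        raise ParseError(f"{path}: duplicated wavenumbers")
    order = np.argsort(x)
    if not np.array_equal(order, np.arange(x.size)):
        log.info("re-sorting %s to ascending wavenumbers", path)
    return Spectrum(x[order], y[order])


# -- JCAMP-DX ----------------------------------------------------------------

def write_jcamp(spectrum: Spectrum, path: str | Path, title: str = "spectrum"):
    """Write one spectrum as JCAMP-DX ``(X++(Y..Y))`` on an affine x-grid."""
    path = Path(path)
    x, y = spectrum.wavenumbers, spectrum.intensities
    steps = np.diff(x)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=0):
        raise ValueError("JCAMP-DX (X++(Y..Y)) export requires a uniform grid")
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={_format_float(x[0])}",
        f"##LASTX={_format_float(x[-1])}",
        f"##DELTAX={_format_float(steps[0])}",
        f"##NPOINTS={x.size}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for start in range(0, y.size, per_line):
        chunk = y[start:start + per_line]
        lines.append(" ".join([_format_float(x[start])] +
                              [_format_float(v) for v in chunk]))
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def read_jcamp(path: str | Path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file in the ``(X++(Y..Y))`` form."""
    path = Path(path)
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                break
            header[key] = value.strip()
            continue
        if in_data:
            parts = line.split()
            try:
                ys.extend(float(v) for v in parts[1:])
            except ValueError:
                raise ParseError(f"{path}: non-numeric y value", line=lineno)
    for required in ("FIRSTX", "DELTAX", "NPOINTS"):
        if required not in header:
            raise ParseError(f"{path}: missing ##{required}= record")
    firstx = float(header["FIRSTX"])
    deltax = float(header["DELTAX"])
    npoints = int(header["NPOINTS"])
    if len(ys) != npoints:
        raise ParseError(
            f"{path}: ##NPOINTS={npoints} but {len(ys)} y values present"
        )
    yfactor = float(header.get("YFACTOR", "1"))
    x = firstx + deltax * np.arange(npoints)
    y = np.array(ys) * yfactor
    if deltax < 0:
        x, y = x[::-1].copy(), y[::-1].copy()
    return Spectrum(x, y)


# -- tabular artifacts -------------------------------------------------------

def write_feature_matrix(features: FeatureMatrix, path: str | Path):
    df = pd.DataFrame(features.values, columns=features.column_names())
    df.insert(0, "label", features.labels)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_split(split: SplitIndices, path: str | Path):
    rows = [{"index": int(i), "role": "train"} for i in split.train]
    rows += [{"index": int(i), "role": "test"} for i in split.test]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json(obj: dict, path: str | Path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
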