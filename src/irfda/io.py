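"""Reading and writing IR spectra and label manifests.

Spectra arrive either as JCAMP-DX files (the NIST WebBook export format)
or as plain two-column CSV.  Labels live in a manifest CSV that assigns
each compound four binary functional-group flags (amide, aniline, benzene,
piperidine) and a train/test split.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GROUPS = ("amide", "aniline", "benzene", "piperidine")

#: Floor applied to transmittance before taking -log10, bounding absorbance.
TRANSMITTANCE_FLOOR = 1e-6


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


class UnsupportedFormatError(SpectrumParseError):
    """Raised when a file uses a JCAMP-DX dialect or unit we do not read."""


class ManifestError(ValueError):
    """Raised when a label manifest fails validation."""


@dataclass(frozen=True)
class Spectrum:
    """One compound's raw IR spectrum: absorbance sampled at wavenumbers.

    Wavenumbers are in cm^-1 and strictly increasing; absorbance is in
    arbitrary units.  Measurement noise is implicit in the values.
    """

    compound_id: str
    wavenumbers: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.ndim != 1 or ab.ndim != 1 or wn.shape != ab.shape:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D")
        if wn.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)


@dataclass(frozen=True)
class LabelRecord:
    """Ground-truth functional-group flags and split for one compound."""

    compound_id: str
    has_amide: bool
    has_aniline: bool
    has_benzene: bool
    has_piperidine: bool
    split: str  # "train" or "test"

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ManifestError(f"unknown split value {self.split!r}")

    @property
    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.has_amide, self.has_aniline, self.has_benzene, self.has_piperidine)


# --------------------------------------------------------------------------
# JCAMP-DX reading
# --------------------------------------------------------------------------

# ASDF pseudo-digit maps (JCAMP-DX 4.24).  SQZ encodes the leading digit of
# an ordinate, DIF the leading digit of a difference from the previous
# ordinate, DUP a repeat count for the previous token.
_SQZ = {c: v for v, c in enumerate("@ABCDEFGHI")}
_SQZ.update({c: -v for v, c in enumerate("@abcdefghi") if v})
_DIF = {c: v for v, c in enumerate("%JKLMNOPQR")}
_DIF.update({c: -v for v, c in enumerate("%jklmnopqr") if v})
_DUP = {c: v for v, c in enumerate("0STUVWXYZs") if v}

_TOKEN_RE = re.compile(
    r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?"  # AFFN number
    r"|[@A-Ia-i%J-Rj-rS-Zs][0-9.]*"  # ASDF pseudo-digit + trailing digits
)


def _num(tok: str, line_no: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise SpectrumParseError(f"non-numeric value {tok!r} on line {line_no}") from None


def _decode_line(tokens: list[str], prev_y: float | None, line_no: int) -> tuple[list[float], bool]:
    """Decode the ordinate tokens of one XYDATA line.

    Returns the ordinates and whether the line ended in DIF mode (so the
    next line's first ordinate is a Y-check to be dropped).  ``prev_y`` is
    the running ordinate carried across lines for DIF continuation.
    """
    ys: list[float] = []
    last_mode = "affn"  # affn | sqz | dif
    last_dif = 0.0
    y = prev_y
    for tok in tokens:
        c = tok[0]
        if c in _SQZ:
            y = _signed(_SQZ[c], tok[1:], line_no)
            ys.append(y)
            last_mode = "sqz"
        elif c in _DIF:
            if y is None:
                raise SpectrumParseError(f"DIF value with no prior ordinate on line {line_no}")
            last_dif = _signed(_DIF[c], tok[1:], line_no)
            y = y + last_dif
            ys.append(y)
            last_mode = "dif"
        elif c in _DUP:
            count = int(_signed(_DUP[c], tok[1:], line_no))
            if not ys and y is None:
                raise SpectrumParseError(f"DUP with no prior value on line {line_no}")
            for _ in range(count - 1):
                if last_mode == "dif":
                    y = y + last_dif
                    ys.append(y)
                else:
                    ys.append(y)
        else:
            y = _num(tok, line_no)
            ys.append(y)
            last_mode = "affn"
    return ys, last_mode == "dif"


def _signed(lead: int, rest: str, line_no: int) -> float:
    digits = str(abs(lead)) + rest
    try:
        val = float(digits)
    except ValueError:
        raise SpectrumParseError(f"bad compressed token digits {rest!r} on line {line_no}") from None
    return -val if lead < 0 else val


def _parse_header(lines: list[str]) -> dict[str, str]:
    header: dict[str, str] = {}
    for ln in lines:
        if ln.startswith("##"):
            key, _, val = ln[2:].partition("=")
            header[key.strip().upper().replace(" ", "")] = val.strip()
    return header


def read_jcamp(path: str | Path, compound_id: str | None = None) -> Spectrum:
    """Read a JCAMP-DX IR spectrum (AFFN, SQZ, DIF and DUP forms).

    Transmittance ordinates are converted to absorbance as -log10(T) with
    T floored at ``TRANSMITTANCE_FLOOR``; XFACTOR/YFACTOR scaling is
    applied; descending abscissae are reversed; duplicate wavenumbers are
    averaged.  Micrometer abscissae are converted to cm^-1.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    header = _parse_header(raw_lines)

    data_key = None
    for key in ("XYDATA", "XYPOINTS"):
        if key in header:
            data_key = key
            break
    if data_key is None:
        if "PEAKTABLE" in header:
            raise UnsupportedFormatError(f"{path}: PEAK TABLE data are not supported")
        raise SpectrumParseError(f"{path}: no XYDATA or XYPOINTS block found")

    xunits = header.get("XUNITS", "1/CM").upper()
    yunits = header.get("YUNITS", "ABSORBANCE").upper()
    xfactor = float(header.get("XFACTOR", "1"))
    yfactor = float(header.get("YFACTOR", "1"))

    if xunits not in ("1/CM", "MICROMETERS"):
        raise UnsupportedFormatError(f"{path}: unsupported XUNITS {xunits!r}")
    if yunits not in ("ABSORBANCE", "TRANSMITTANCE", "%TRANSMITTANCE", "TRANSMITTANCE(%)"):
        raise UnsupportedFormatError(f"{path}: unsupported YUNITS {yunits!r}")

    # locate the data block
    start = next(
        i for i, ln in enumerate(raw_lines) if ln.upper().startswith(f"##{data_key}")
    )
    block: list[tuple[int, str]] = []
    for offset, ln in enumerate(raw_lines[start + 1 :], start + 2):
        stripped = ln.split("$$")[0].strip()
        if stripped.startswith("##"):
            break
        if stripped:
            block.append((offset, stripped))
    if not block:
        raise SpectrumParseError(f"{path}: empty {data_key} block")

    xs: list[float] = []
    ys: list[float] = []
    if data_key == "XYPOINTS":
        for line_no, ln in block:
            for pair in re.split(r"[;]", ln):
                pair = pair.strip()
                if not pair:
                    continue
                parts = re.split(r"[,\s]+", pair)
                if len(parts) != 2:
                    raise SpectrumParseError(f"{path}: malformed XY pair on line {line_no}")
                xs.append(_num(parts[0], line_no))
                ys.append(_num(parts[1], line_no))
    else:
        # (X++(Y..Y)) form: each line is an abscissa followed by ordinates.
        npoints = int(float(header["NPOINTS"])) if "NPOINTS" in header else None
        firstx = float(header["FIRSTX"]) if "FIRSTX" in header else None
        lastx = float(header["LASTX"]) if "LASTX" in header else None
        deltax: float | None = None
        if npoints and npoints > 1 and firstx is not None and lastx is not None:
            deltax = (lastx - firstx) / (npoints - 1)

        # each row: (line abscissa, ordinates after any Y-check drop,
        # whether a check was dropped — the remaining ordinates then start
        # one spacing step after the line abscissa)
        rows: list[tuple[float, list[float], bool]] = []
        prev_y: float | None = None
        check_pending = False
        for line_no, ln in block:
            tokens = _TOKEN_RE.findall(ln)
            if not tokens:
                raise SpectrumParseError(f"{path}: unparseable data on line {line_no}")
            x0 = _num(tokens[0], line_no)
            line_ys, ended_dif = _decode_line(tokens[1:], prev_y, line_no)
            if not line_ys:
                raise SpectrumParseError(f"{path}: data line {line_no} has no ordinates")
            dropped = False
            if check_pending:
                # first ordinate repeats the previous line's last (Y-check)
                if not math.isclose(line_ys[0], prev_y, rel_tol=1e-6, abs_tol=1e-6):
                    raise SpectrumParseError(
                        f"{path}: Y-check failed on line {line_no} "
                        f"({line_ys[0]!r} vs {prev_y!r})"
                    )
                line_ys = line_ys[1:]
                dropped = True
            prev_y = line_ys[-1] if line_ys else prev_y
            check_pending = ended_dif
            rows.append((x0, line_ys, dropped))

        if deltax is None:
            # infer spacing from consecutive line starts; when the next line
            # begins with a Y-check its abscissa coincides with this line's
            # last ordinate rather than one step past it
            if len(rows) > 1:
                spans = []
                for i in range(len(rows) - 1):
                    n_i = len(rows[i][1]) + (1 if rows[i][2] else 0)
                    steps = n_i - (1 if rows[i + 1][2] else 0)
                    spans.append((rows[i + 1][0] - rows[i][0]) / max(steps, 1))
                deltax = float(np.mean(spans))
            else:
                if lastx is None:
                    raise SpectrumParseError(f"{path}: cannot determine abscissa spacing")
                deltax = (lastx - rows[0][0]) / max(len(rows[0][1]) - 1, 1)
        for x0, line_ys, dropped in rows:
            start = x0 + deltax if dropped else x0
            for j, y in enumerate(line_ys):
                xs.append(start + j * deltax)
                ys.append(y)

    x = np.asarray(xs, dtype=float) * xfactor
    y = np.asarray(ys, dtype=float) * yfactor

    if xunits == "MICROMETERS":
        if np.any(x <= 0):
            raise SpectrumParseError(f"{path}: non-positive micrometer abscissa")
        x = 1e4 / x

    if yunits != "ABSORBANCE":
        t = y / 100.0 if "%" in yunits or "(%)" in yunits else y
        t = np.clip(t, TRANSMITTANCE_FLOOR, None)
        y = -np.log10(t)

    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    x, y = _merge_duplicates(x, y)
    return Spectrum(compound_id or path.stem, x, y)


def _merge_duplicates(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average ordinates that share a wavenumber (order-independent)."""
    ux, inverse = np.unique(x, return_inverse=True)
    if ux.size == x.size:
        return x, y
    sums = np.zeros(ux.size)
    counts = np.zeros(ux.size)
    np.add.at(sums, inverse, y)
    np.add.at(counts, inverse, 1.0)
    return ux, sums / counts


# --------------------------------------------------------------------------
# CSV spectra
# --------------------------------------------------------------------------

def read_csv_spectrum(path: str | Path, compound_id: str | None = None) -> Spectrum:
    """Read a two-column (wavenumber, absorbance) CSV; header row optional."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SpectrumParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 2:
        raise SpectrumParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    # drop a header row if the first row is non-numeric
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:]
    try:
        arr = df.astype(float).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SpectrumParseError(f"{path}: non-numeric cell ({exc})") from exc
    if arr.shape[0] < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    order = np.argsort(arr[:, 0], kind="stable")
    x, y = _merge_duplicates(arr[order, 0], arr[order, 1])
    return Spectrum(compound_id or path.stem, x, y)


def write_csv_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column CSV with a header row."""
    df = pd.DataFrame(
        {"wavenumber": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


# --------------------------------------------------------------------------
# Label manifests
# --------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["compound_id", "amide", "aniline", "benzene", "piperidine", "split"]
_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no"}


def load_manifest(path: str | Path) -> list[LabelRecord]:
    """Load and validate a label manifest CSV.

    Columns: compound_id, amide, aniline, benzene, piperidine, split.
    Flags accept 0/1 or true/false; split must be train or test;
    compound ids must be unique.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing columns {missing}")
    dupes = df["compound_id"][df["compound_id"].duplicated()].tolist()
    if dupes:
        raise ManifestError(f"{path}: duplicate compound ids {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            LabelRecord(
                compound_id=str(row["compound_id"]),
                has_amide=_parse_flag(row["amide"], path),
                has_aniline=_parse_flag(row["aniline"], path),
                has_benzene=_parse_flag(row["benzene"], path),
                has_piperidine=_parse_flag(row["piperidine"], path),
                split=str(row["split"]).strip().lower(),
            )
        )
    return records


def write_manifest(records: Iterable[LabelRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "amide": int(r.has_amide),
                "aniline": int(r.has_aniline),
                "benzene": int(r.has_benzene),
                "piperidine": int(r.has_piperidine),
                "split": r.split,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def _parse_flag(value: object, path: str | Path) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ManifestError(f"{path}: invalid flag value {value!r}")
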