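"""File formats: spectra CSV + manifest, FASTA, TSV traces, fixtures.

Spectra travel as CSV with a ``wavelength_nm`` first column and one
column per titration point headed ``r<ratio>`` (``r0``, ``r0.25`` ...
``r7``), accompanied by a plain-text key:value manifest giving
``ligand_total_uM`` and ``ratios``.  All outputs use Unix newlines and
9-significant-digit decimals so that identical inputs yield identical
bytes.

The package ships two NOE contact tables and the study's thirteen
palindromic sequences as plain-text fixtures under ``dnabind/data``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chemometrics import TitrationSeries
from .errors import ParseError
from .occupancy import GeometricTrace

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_manifest",
    "write_manifest",
    "read_fasta",
    "read_trace_tsv",
    "write_trace_tsv",
    "packaged_noe_table",
    "packaged_sequences",
]

_FMT = "%.9g"


def _format_ratio(r: float) -> str:
    return f"r{r:.9g}"


def read_manifest(path: str | Path) -> dict:
    """Parse a key:value manifest with ``ligand_total_uM`` and ``ratios``."""
    entries: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ParseError(f"{path}:{line_no}: expected 'key: value'")
        key, value = line.split(":", 1)
        entries[key.strip()] = value.strip()
    try:
        ligand_total = float(entries["ligand_total_uM"])
        ratios = [float(tok) for tok in entries["ratios"].split(",")]
    except KeyError as exc:
        raise ParseError(f"manifest {path} missing key {exc}") from exc
    except ValueError as exc:
        raise ParseError(f"manifest {path}: non-numeric value ({exc})") from exc
    return {"ligand_total_uM": ligand_total, "ratios": ratios}


def write_manifest(path: str | Path, ligand_total: float,
                   ratios: list[float] | np.ndarray) -> None:
    text = (
        f"ligand_total_uM: {ligand_total:.9g}\n"
        "ratios: " + ", ".join(f"{r:.9g}" for r in ratios) + "\n"
    )
    Path(path).write_text(text)


def read_spectra_csv(path: str | Path, manifest: str | Path) -> TitrationSeries:
    """Read a spectra CSV and its manifest into a validated series.

    The ``r<ratio>`` column headers are cross-checked against the
    manifest's ratio list.
    """
    try:
        frame = pd.read_csv(path)
    except ValueError as exc:
        raise ParseError(f"cannot parse spectra CSV {path}: {exc}") from exc
    if frame.columns[0] != "wavelength_nm":
        raise ParseError(
            f"{path}: first column must be 'wavelength_nm', got "
            f"{frame.columns[0]!r}"
        )
    meta = read_manifest(manifest)
    ratios = meta["ratios"]
    point_cols = list(frame.columns[1:])
    if len(point_cols) != len(ratios):
        raise ParseError(
            f"{path}: {len(point_cols)} spectrum columns but manifest lists "
            f"{len(ratios)} ratios"
        )
    expected = [_format_ratio(r) for r in ratios]
    if point_cols != expected:
        raise ParseError(
            f"{path}: column headers {point_cols} do not match manifest "
            f"ratios (expected {expected})"
        )
    values = frame[point_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-numeric or non-finite absorbance cells")
    return TitrationSeries(
        wavelengths=frame["wavelength_nm"].to_numpy(dtype=float),
        absorbance=values,
        ligand_total=meta["ligand_total_uM"],
        dna_ratios=np.asarray(ratios, dtype=float),
        absorbance_floor=min(-0.01, float(values.min()) - 1e-12),
    )


def write_spectra_csv(path: str | Path, series: TitrationSeries) -> None:
    header = ["wavelength_nm"] + [_format_ratio(r) for r in series.dna_ratios]
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for i, wl in enumerate(series.wavelengths):
            row = [_FMT % wl] + [_FMT % a for a in series.absorbance[i]]
            fh.write(",".join(row) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, uppercased sequence)`` pairs."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    ids = [rid for rid, _ in records]
    dupes = {rid for rid in ids if ids.count(rid) > 1}
    if dupes:
        raise ParseError(f"{path}: duplicate record IDs {sorted(dupes)}")
    return records


def read_trace_tsv(path: str | Path) -> GeometricTrace:
    """Read a per-frame geometry TSV (distance_nm [, angle_deg])."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty trace file")
    header = [h.strip() for h in lines[0].split("\t")]
    if header[0] != "distance_nm":
        raise ParseError(
            f"{path}: first column must be 'distance_nm', got {header[0]!r}"
        )
    has_angle = len(header) > 1 and header[1] == "angle_deg"
    frames: list[tuple[float, float | None]] = []
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        try:
            d = float(cells[0])
            a = float(cells[1]) if has_angle and len(cells) > 1 and cells[1].strip() else None
        except ValueError as exc:
            raise ParseError(f"{path}:{line_no}: non-numeric cell") from exc
        frames.append((d, a))
    return GeometricTrace(tuple(frames))


def write_trace_tsv(path: str | Path, trace: GeometricTrace) -> None:
    has_angle = any(a is not None for _, a in trace.frames)
    with open(path, "w", newline="\n") as fh:
        fh.write("distance_nm\tangle_deg\n" if has_angle else "distance_nm\n")
        for d, a in trace.frames:
            if has_angle:
                fh.write((_FMT % d) + "\t" + ((_FMT % a) if a is not None else "") + "\n")
            else:
                fh.write((_FMT % d) + "\n")


def packaged_noe_table(name: str) -> str:
    """Text of a packaged NOE contact table: ``"table2"`` (D2L/D3L
    contacts) or ``"table4"`` (B2L contacts)."""
    return (
        resources.files("dnabind.data").joinpath(f"{name}_noe.tsv").read_text()
    )


def packaged_sequences() -> list[tuple[str, str]]:
    """The thirteen palindromic study sequences (D1-D9, B1-B4)."""
    path = resources.files("dnabind.data").joinpath("paper_sequences.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)
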