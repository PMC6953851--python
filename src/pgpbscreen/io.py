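"""Readers and writers for the pipeline's tab-separated dialects and FASTA.

All tables are UTF-8, tab-separated, "." decimal separator.  Not-detected
trait values are written as the empty cell and read back as ``None``; the
token ``ND`` is accepted on input.  Numeric values are preserved to at
least six significant digits on a round trip.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    Alignment,
    BandProfile,
    BiomassObservation,
    Collection,
    DilutionSeries,
    Medium,
    Soil,
    Source,
    Species,
    StrainRecord,
    TraitMeasurement,
    ValidationError,
    validate_collection,
)

STRAINS_COLUMNS = ["strain_id", "source", "soil", "medium", "genus"]
TRAITS_COLUMNS = ["strain_id", "iaa", "fepo4", "alpo4", "siderophore_index"]
BIOMASS_COLUMNS = ["species", "treatment", "replicate", "rdw", "sdw"]
DILUTIONS_COLUMNS = ["sample_id", "amount_g", "n_vials", "n_positive"]
BANDS_COLUMNS = ["strain_id", "bands_bp"]

_ND_TOKENS = {"", "ND", "nd", "NA"}


class TableFormatError(ValueError):
    """Malformed table row; the message names file, line and field."""


def _fmt(x: float) -> str:
    """Shortest decimal form that reads back to the identical float."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _parse_float(token: str, path: Path, line: int, fieldname: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise TableFormatError(f"{path}:{line}: field {fieldname!r}: not a number: {token!r}")


def _parse_optional(token: str, path: Path, line: int, fieldname: str) -> Optional[float]:
    if token.strip() in _ND_TOKENS:
        return None
    return _parse_float(token, path, line, fieldname)


def _read_rows(path: Path, columns: list[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TableFormatError(f"{path}:1: empty file, expected header {columns}")
        if header != columns:
            raise TableFormatError(f"{path}:1: header {header} does not match expected {columns}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(columns):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(columns)} fields, got {len(row)}"
                )
            yield lineno, row


def read_strains(path: Path) -> list[StrainRecord]:
    out = []
    for lineno, row in _read_rows(path, STRAINS_COLUMNS):
        sid, source, soil, medium, genus = (c.strip() for c in row)
        try:
            rec = StrainRecord(sid, Source(source), Soil(soil), Medium(medium), genus or "unclassified")
        except ValueError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}")
        out.append(rec)
    return out


def read_traits(path: Path) -> list[TraitMeasurement]:
    out = []
    for lineno, row in _read_rows(path, TRAITS_COLUMNS):
        sid = row[0].strip()
        vals = [
            _parse_optional(row[i], path, lineno, TRAITS_COLUMNS[i]) for i in range(1, 5)
        ]
        try:
            out.append(TraitMeasurement(sid, *vals))
        except ValidationError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}")
    return out


def read_biomass(path: Path) -> list[BiomassObservation]:
    out = []
    for lineno, row in _read_rows(path, BIOMASS_COLUMNS):
        try:
            sp = Species(row[0].strip())
        except ValueError:
            raise TableFormatError(f"{path}:{lineno}: field 'species': unknown value {row[0]!r}")
        try:
            rep = int(row[2])
        except ValueError:
            raise TableFormatError(f"{path}:{lineno}: field 'replicate': not an integer: {row[2]!r}")
        rdw = _parse_float(row[3], path, lineno, "rdw")
        sdw = _parse_float(row[4], path, lineno, "sdw")
        try:
            out.append(BiomassObservation(sp, row[1].strip(), rep, rdw, sdw))
        except ValidationError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}")
    return out


def read_dilutions(path: Path) -> list[DilutionSeries]:
    grouped: dict[str, list[tuple[float, int, int]]] = {}
    order: list[str] = []
    for lineno, row in _read_rows(path, DILUTIONS_COLUMNS):
        sid = row[0].strip()
        amount = _parse_float(row[1], path, lineno, "amount_g")
        try:
            n, g = int(row[2]), int(row[3])
        except ValueError:
            raise TableFormatError(f"{path}:{lineno}: vial counts must be integers")
        if sid not in grouped:
            grouped[sid] = []
            order.append(sid)
        grouped[sid].append((amount, n, g))
    out = []
    for sid in order:
        rows = grouped[sid]
        try:
            out.append(
                DilutionSeries(
                    sid,
                    tuple(r[0] for r in rows),
                    tuple(r[1] for r in rows),
                    tuple(r[2] for r in rows),
                )
            )
        except ValidationError as exc:
            raise TableFormatError(f"{path}: sample {sid!r}: {exc}")
    return out


def read_bands(path: Path) -> list[BandProfile]:
    out = []
    for lineno, row in _read_rows(path, BANDS_COLUMNS):
        sid = row[0].strip()
        tokens = [t for t in row[1].split(",") if t.strip()]
        bands = tuple(
            sorted(_parse_float(t, path, lineno, "bands_bp") for t in tokens)
        )
        try:
            out.append(BandProfile(sid, bands))
        except ValidationError as exc:
            raise TableFormatError(f"{path}:{lineno}: {exc}")
    return out


def read_alignment(path: Path) -> Alignment:
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return Alignment(tuple(records))


def write_alignment(alignment: Alignment, path: Path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in alignment.sequences]
    SeqIO.write(records, str(path), "fasta")


def _write_table(path: Path, columns: list[str], rows: Iterable[list[str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)


def write_collection(collection: Collection, out_dir: Path) -> dict[str, Path]:
    """Write a collection into ``out_dir`` as the standard table dialects.

    Returns a mapping from table name to the written path.  An empty
    collection yields headers-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {name: out_dir / f"{name}.tsv" for name in
             ("strains", "traits", "biomass", "dilutions", "bands")}

    _write_table(paths["strains"], STRAINS_COLUMNS, (
        [s.strain_id, s.source.value, s.soil.value, s.medium.value, s.genus]
        for s in collection.strains
    ))
    _write_table(paths["traits"], TRAITS_COLUMNS, (
        [t.strain_id] + ["" if v is None else _fmt(v)
                         for v in (t.iaa, t.fepo4, t.alpo4, t.siderophore_index)]
        for t in collection.traits
    ))
    _write_table(paths["biomass"], BIOMASS_COLUMNS, (
        [o.species.value, o.treatment, str(o.replicate), _fmt(o.rdw), _fmt(o.sdw)]
        for o in collection.biomass
    ))
    _write_table(paths["dilutions"], DILUTIONS_COLUMNS, (
        [d.sample_id, _fmt(a), str(n), str(g)]
        for d in collection.dilutions
        for a, n, g in zip(d.amounts, d.n_vials, d.n_positive)
    ))
    _write_table(paths["bands"], BANDS_COLUMNS, (
        [b.strain_id, ",".join(_fmt(x) for x in b.bands)] for b in collection.bands
    ))
    if collection.alignment is not None:
        fasta = out_dir / "alignment.fasta"
        write_alignment(collection.alignment, fasta)
        paths["alignment"] = fasta
    return paths


def read_collection(in_dir: Path, validate: bool = True) -> tuple[Collection, list[str]]:
    """Read a collection directory written by :func:`write_collection`.

    Returns the typed collection and the list of cross-reference warnings.
    """
    in_dir = Path(in_dir)
    collection = Collection(
        strains=read_strains(in_dir / "strains.tsv"),
        traits=read_traits(in_dir / "traits.tsv"),
        biomass=read_biomass(in_dir / "biomass.tsv"),
        dilutions=read_dilutions(in_dir / "dilutions.tsv"),
        bands=read_bands(in_dir / "bands.tsv"),
    )
    fasta = in_dir / "alignment.fasta"
    if fasta.exists():
        collection.alignment = read_alignment(fasta)
    warnings = validate_collection(collection) if validate else []
    return collection, warnings
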