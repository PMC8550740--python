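"""Sequence and survey-record I/O plus genetic-code translation.

All sequence coordinates in this package are 0-based with half-open windows.
FASTA is written wrapped at 70 columns; any wrapping is accepted on read.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Data import CodonTable

IUPAC_NT = set("ACGTRYSWKMBDHVN-")

SURVEY_COLUMNS = [
    "sample_id",
    "host_scientific",
    "host_common",
    "host_family",
    "region",
    "lat",
    "lon",
    "whitefly_ids",
]


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""


class SurveySchemaError(ValueError):
    """Survey TSV missing required columns or containing invalid rows."""


@dataclass
class BarcodeSequence:
    """One nucleotide barcode read.

    Attributes
    ----------
    id : str
        Unique sequence identifier.
    nt : str
        Uppercase nucleotide string over the IUPAC alphabet (may contain
        ambiguity codes or ``-`` gaps).
    sample_id : str or None
        Optional link to the collection record this fly came from.
    """

    id: str
    nt: str
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not self.nt:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.nt) - IUPAC_NT
        if bad:
            raise ValueError(f"{self.id}: non-IUPAC characters {sorted(bad)}")


@dataclass
class CollectionRecord:
    """One host-plant/site collection: by design three adult whiteflies."""

    sample_id: str
    host_scientific: str
    host_common: str
    host_family: str
    region: str
    whitefly_ids: list[str]
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if not self.whitefly_ids:
            raise ValueError(f"{self.sample_id}: whitefly_ids must be non-empty")
        if not self.host_scientific:
            # hosts known only by a local common name are kept, labelled Unknown
            self.host_scientific = "Unknown"


@dataclass
class GeneticCode:
    """An NCBI translation table as a 64-entry codon map plus stop set."""

    table_id: int
    forward: dict[str, str] = field(repr=False)
    stops: frozenset[str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.forward) + len(self.stops) != 64:
            raise ValueError("codon map + stop set must cover all 64 codons")
        if self.stops & set(self.forward):
            raise ValueError("stop set overlaps amino-acid assignments")

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        tab = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(
            table_id=table_id,
            forward=dict(tab.forward_table),
            stops=frozenset(tab.stop_codons),
        )


#: Standard nuclear code.
STANDARD_CODE = GeneticCode.from_ncbi(1)
#: Invertebrate mitochondrial code — the default for mtCO1 work
#: (TGA=Trp, AGA/AGG=Ser, ATA=Met).
INVERT_MITO_CODE = GeneticCode.from_ncbi(5)


def read_fasta(path: str | Path) -> list[BarcodeSequence]:
    """Read a FASTA file into BarcodeSequence records, order preserved.

    Sequences are uppercased. Raises FastaParseError (with line number) on
    content before the first header or illegal sequence characters; raises
    ValueError on duplicate ids.
    """
    records: list[BarcodeSequence] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        nt = "".join(chunks)
        if not nt:
            raise FastaParseError(f"line {header_line}: entry '{header}' has no sequence")
        try:
            rec = BarcodeSequence(id=header, nt=nt)
        except ValueError as exc:
            raise FastaParseError(f"line {header_line}: {exc}") from exc
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id '{rec.id}'")
        seen.add(rec.id)
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(f"line {lineno}: sequence data before any header")
                chunks.append(line.upper())
    flush()
    return records


def write_fasta(records: list[BarcodeSequence], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, sequence lines wrapped at `width` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.nt), width):
                fh.write(rec.nt[i : i + width] + "\n")


def read_survey_records(path: str | Path) -> list[CollectionRecord]:
    """Read the survey TSV (documented header, see SURVEY_COLUMNS).

    whitefly_ids is comma-separated. lat/lon may be empty; non-numeric values
    raise ValueError. Duplicate sample_ids are rejected.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SurveySchemaError("empty survey file")
        missing = [c for c in SURVEY_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SurveySchemaError(f"missing required columns: {missing}")
        records: list[CollectionRecord] = []
        seen: set[str] = set()
        for row in reader:
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValueError(f"duplicate sample_id '{sid}'")
            seen.add(sid)

            def coord(key: str) -> float | None:
                val = (row[key] or "").strip()
                if not val:
                    return None
                try:
                    return float(val)
                except ValueError:
                    raise ValueError(f"sample {sid}: non-numeric {key} '{val}'") from None

            records.append(
                CollectionRecord(
                    sample_id=sid,
                    host_scientific=row["host_scientific"].strip(),
                    host_common=row["host_common"].strip(),
                    host_family=row["host_family"].strip() or "Unknown",
                    region=row["region"].strip(),
                    whitefly_ids=[w.strip() for w in row["whitefly_ids"].split(",") if w.strip()],
                    lat=coord("lat"),
                    lon=coord("lon"),
                )
            )
    return records


def write_survey_records(records: list[CollectionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SURVEY_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.sample_id,
                    rec.host_scientific,
                    rec.host_common,
                    rec.host_family,
                    rec.region,
                    "" if rec.lat is None else repr(rec.lat),
                    "" if rec.lon is None else repr(rec.lon),
                    ",".join(rec.whitefly_ids),
                ]
            )


def translate(
    nt: str, frame_offset: int = 0, code: GeneticCode = INVERT_MITO_CODE
) -> tuple[str, list[int]]:
    """Translate a gap-free nucleotide string from the given frame.

    Returns the peptide and the 0-based peptide indices of stop codons
    (written '*'). A trailing partial codon is dropped. Any codon containing
    a non-ACGT symbol translates to 'X', never to a stop: a Sanger ambiguity
    must not be able to trigger the premature-stop filter downstream.
    """
    if "-" in nt:
        raise ValueError("translate requires a gap-free sequence")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    if frame_offset >= len(nt):
        raise ValueError("frame_offset beyond sequence length")
    effective = nt[frame_offset:]
    n_codons = len(effective) // 3
    if n_codons == 0:
        raise ValueError("no complete codon in effective sequence")
    peptide = []
    stops: list[int] = []
    for i in range(n_codons):
        codon = effective[3 * i : 3 * i + 3]
        if set(codon) - set("ACGT"):
            peptide.append("X")
        elif codon in code.stops:
            peptide.append("*")
            stops.append(i)
        else:
            peptide.append(code.forward[codon])
    return "".join(peptide), stops
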