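"""Reading, writing and normalisation of immunopeptidome data.

This module turns search-engine exports (TSV/CSV peptide tables), FASTA
proteomes, haplotype tables and plain reference peptide lists into the
package's internal data model.  Sequences are normalised to the 20
canonical amino-acid letters: PTM annotations in parentheses (PEAKS style,
e.g. ``M(+15.99)``) are stripped, lowercase flanking annotations removed,
and everything uppercased.  Records that still contain non-canonical
residues are rejected with a logged warning, never silently kept.
"""

from __future__ import annotations

import json
import logging
import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

_CANONICAL_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
_PAREN_RE = re.compile(r"\([^()]*\)|\[[^\[\]]*\]")
_FLANK_RE = re.compile(r"^[a-z.\-]+|[a-z.\-]+$")

TISSUE_LABELS = ("tumor", "benign", "cell_line")


class FormatError(ValueError):
    """Raised for malformed input files (missing columns, bad FASTA, ...)."""


class AlleleFormatError(ValueError):
    """Raised when an MHC allele name cannot be parsed."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideRecord:
    """A single eluted-peptide observation within one run."""

    sequence: str
    source_proteins: tuple[str, ...] = ()
    intensity: float | None = None
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if not _CANONICAL_RE.match(self.sequence):
            raise ValueError(f"non-canonical sequence: {self.sequence!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SampleRun:
    """One immunopeptidomics replicate: a set of unique peptides plus its
    MHC haplotype and tissue label.

    Duplicate sequences passed to the constructor are collapsed: intensity
    aggregated by max, source accessions unioned.
    """

    sample_id: str
    replicate_id: str
    peptides: dict[str, PeptideRecord] = field(default_factory=dict)
    haplotype: tuple[str, ...] = ()
    tissue_label: str = "cell_line"

    def __post_init__(self) -> None:
        if self.tissue_label not in TISSUE_LABELS:
            raise ValueError(f"tissue_label must be one of {TISSUE_LABELS}")
        if not isinstance(self.peptides, dict):
            records, self.peptides = list(self.peptides), {}
            for rec in records:
                self.add(rec)

    @property
    def run_id(self) -> str:
        return f"{self.sample_id}/{self.replicate_id}"

    def add(self, record: PeptideRecord) -> None:
        """Insert a record, collapsing duplicates (max intensity, union of
        source proteins)."""
        prev = self.peptides.get(record.sequence)
        if prev is None:
            self.peptides[record.sequence] = record
            return
        intensities = [x for x in (prev.intensity, record.intensity) if x is not None]
        merged = replace(
            prev,
            intensity=max(intensities) if intensities else None,
            source_proteins=tuple(
                sorted(set(prev.source_proteins) | set(record.source_proteins))
            ),
        )
        self.peptides[record.sequence] = merged

    @property
    def sequences(self) -> frozenset[str]:
        return frozenset(self.peptides)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides.values())


@dataclass
class ProteinDb:
    """Accession -> sequence map for a protein database."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for acc, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"zero-length sequence for accession {acc}")
            if not _CANONICAL_RE.match(seq):
                raise FormatError(f"non-canonical residues in {acc}")

    def length(self, accession: str) -> int:
        return len(self.sequences[accession])

    @property
    def lengths(self) -> dict[str, int]:
        return {acc: len(seq) for acc, seq in self.sequences.items()}

    def __contains__(self, accession: str) -> bool:
        return accession in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, accession: str) -> str:
        return self.sequences[accession]


# ---------------------------------------------------------------------------
# sequence / accession normalisation
# ---------------------------------------------------------------------------


def normalize_sequence(raw: str) -> str:
    """Strip PTM annotations and flanking residue notation; uppercase.

    Removes any parenthesised (or bracketed) substring, then lowercase
    flanking annotations and ``.`` separators at either end.
    """
    s = _PAREN_RE.sub("", raw.strip())
    while True:
        stripped = _FLANK_RE.sub("", s)
        if stripped == s:
            break
        s = stripped
    return s.upper()


def parse_accession(token: str) -> str:
    """UniProt ``sp|ACC|NAME`` headers yield the middle field; anything else
    is used verbatim up to the first whitespace."""
    token = token.strip().split()[0] if token.strip() else ""
    if "|" in token:
        fields = token.split("|")
        if len(fields) >= 3 and fields[0] in ("sp", "tr"):
            return fields[1]
        return fields[-1] if fields[0] in ("sp", "tr") else fields[0]
    return token


_HUMAN_RE = re.compile(r"^(?:HLA-)?([A-C])\*?(\d{2,3}):(\d{2,3})$")
_MOUSE_RE = re.compile(r"^H-?2-?([KDLQ])([a-z])$")


def normalize_allele(name: str) -> str:
    """Canonicalise an MHC class I allele name.

    Human dialects ``HLA-A*02:01`` / ``HLA-A02:01`` / ``A*02:01`` /
    ``A02:01`` all map to ``A02:01``; murine ``H-2Kd`` / ``H2-Kd`` map to
    ``H2-Kd``.  Idempotent on its own output.
    """
    s = name.strip()
    m = _HUMAN_RE.match(s)
    if m:
        locus, group, protein = m.groups()
        return f"{locus}{group}:{protein}"
    m = _MOUSE_RE.match(s)
    if m:
        locus, hap = m.groups()
        return f"H2-{locus}{hap}"
    raise AlleleFormatError(f"unparseable allele name: {name!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    "generic_tsv": {
        "peptide": "peptide",
        "protein": "protein",
        "sample": "sample",
        "replicate": "replicate",
        "intensity": "intensity",
    },
    "peaks_export": {
        "peptide": "Peptide",
        "protein": "Accession",
        "sample": "Sample",
        "replicate": "Replicate",
        "intensity": "Area",
    },
}


def read_peptide_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    column_map: Mapping[str, str] | None = None,
    haplotypes: Mapping[str, tuple[str, ...]] | None = None,
    tissue_labels: Mapping[str, str] | None = None,
) -> list[SampleRun]:
    """Read a search-engine peptide export into a list of ``SampleRun``.

    ``column_map`` overrides the dialect's column names (keys: peptide,
    protein, sample, replicate, intensity).  ``haplotypes`` and
    ``tissue_labels`` attach per-sample metadata.  Rows whose normalised
    sequence still contains non-canonical residues are rejected with a
    warning and counted in the log.
    """
    path = Path(path)
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = dict(_DIALECT_COLUMNS[dialect])
    if column_map:
        cols.update(column_map)

    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    for key in ("peptide", "protein", "sample", "replicate"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column: {cols[key]!r}")
    has_intensity = cols["intensity"] in df.columns

    runs: dict[tuple[str, str], SampleRun] = {}
    n_rejected = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        seq = normalize_sequence(str(row[cols["peptide"]]))
        sample = str(row[cols["sample"]]).strip()
        replicate = str(row[cols["replicate"]]).strip()
        if not seq or not _CANONICAL_RE.match(seq):
            n_rejected += 1
            logger.warning(
                "rejected non-canonical peptide %r in run %s/%s",
                row[cols["peptide"]], sample, replicate,
            )
            continue
        raw_prot = row[cols["protein"]]
        accessions = tuple(
            sorted(
                {parse_accession(tok) for tok in re.split(r"[;,]", str(raw_prot)) if tok.strip()}
            )
        ) if pd.notna(raw_prot) else ()
        intensity = None
        if has_intensity and pd.notna(row[cols["intensity"]]):
            intensity = float(row[cols["intensity"]])
        key = (sample, replicate)
        if key not in runs:
            runs[key] = SampleRun(
                sample_id=sample,
                replicate_id=replicate,
                haplotype=tuple(haplotypes.get(sample, ())) if haplotypes else (),
                tissue_label=(tissue_labels or {}).get(sample, "cell_line"),
            )
        runs[key].add(
            PeptideRecord(seq, accessions, intensity, sample, replicate)
        )
    if n_rejected:
        logger.warning("rejected %d record(s) with non-canonical residues", n_rejected)
    return [runs[k] for k in sorted(runs)]


def write_peptide_table(runs: Iterable[SampleRun], path: str | Path) -> None:
    """Write runs back to a generic TSV (columns: peptide, protein, sample,
    replicate, intensity)."""
    rows = []
    for run in runs:
        for rec in sorted(run, key=lambda r: r.sequence):
            rows.append(
                {
                    "peptide": rec.sequence,
                    "protein": ";".join(rec.source_proteins),
                    "sample": run.sample_id,
                    "replicate": run.replicate_id,
                    "intensity": rec.intensity,
                }
            )
    pd.DataFrame(rows, columns=["peptide", "protein", "sample", "replicate", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | Path) -> ProteinDb:
    """Parse a FASTA proteome into a :class:`ProteinDb`.

    The accession is the header token up to the first whitespace; UniProt
    ``sp|ACC|NAME`` headers contribute the middle field.  Duplicate
    accessions and empty files are format errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        acc = parse_accession(record.id)
        if acc in sequences:
            raise FormatError(f"duplicate accession: {acc}")
        sequences[acc] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return ProteinDb(sequences)


def write_fasta(db: ProteinDb, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(db.sequences):
            fh.write(f">{acc}\n{db.sequences[acc]}\n")


def read_haplotype_table(path: str | Path) -> dict[str, tuple[str, ...]]:
    """TSV of ``sample_id<TAB>comma-separated alleles`` -> normalised map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("haplotype table needs sample_id and allele columns")
    out: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        alleles = tuple(
            normalize_allele(a) for a in str(row.iloc[1]).split(",") if a.strip()
        )
        out[str(row.iloc[0]).strip()] = alleles
    return out


def write_haplotype_table(haplotypes: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\talleles\n")
        for sample in sorted(haplotypes):
            fh.write(f"{sample}\t{','.join(haplotypes[sample])}\n")


def read_reference_set(path: str | Path) -> frozenset[str]:
    """Plain peptide-per-line reference ligand list (IEDB-style export)."""
    peptides = set()
    with open(path) as fh:
        for line in fh:
            seq = line.strip().upper()
            if seq:
                peptides.add(seq)
    return frozenset(peptides)


def run_manifest(runs: Iterable[SampleRun]) -> str:
    """JSON manifest of runs (ids, sizes, haplotypes, tissue labels)."""
    entries = [
        {
            "sample_id": r.sample_id,
            "replicate_id": r.replicate_id,
            "n_peptides": len(r),
            "haplotype": list(r.haplotype),
            "tissue_label": r.tissue_label,
        }
        for r in runs
    ]
    return json.dumps({"runs": entries}, indent=2, sort_keys=True)
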