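"""Readers and writers for peptide identification reports and protein databases.

The canonical input is a tab-separated PSM (peptide-spectrum match) table with
columns ``spectrum_id``, ``peptide``, ``sp_score``, ``probability``,
``proteins`` (";"-separated accessions) and ``peptide_mass``.  A best-effort
subset reader for pepXML (PeptideProphet output) is provided for
interoperability with real search-engine pipelines.  Protein databases are
standard FASTA; the accession is the first whitespace-delimited token of the
defline.

This module also builds the bipartite peptide<->protein index (two mutually
transposed hash maps) that the inference loop traverses.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: required header of the canonical PSM TSV dialect
PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "sp_score",
    "probability",
    "proteins",
    "peptide_mass",
)


class ReportFormatError(ValueError):
    """A report file violates the documented dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, residue alphabet, ...)."""


def _check_sequence(seq: str) -> None:
    bad = set(seq) - VALID_RESIDUES
    if not seq or bad:
        raise ValidationError(
            f"invalid peptide sequence {seq!r}: "
            + ("empty" if not seq else f"illegal residues {sorted(bad)}")
        )


@dataclass(frozen=True)
class PSMRecord:
    """One spectrum-to-peptide match from a search-engine report.

    ``sp_score`` is the Sequest preliminary score Sp — the summed intensity of
    matched signal peaks, factored by the matched/theoretical fragment ratio —
    which this package uses as the peptide intensity unit.
    ``initial_probability`` is the PeptideProphet-style posterior that the
    match is correct.
    """

    spectrum_id: str
    peptide_sequence: str
    sp_score: float
    initial_probability: float
    assigned_proteins: tuple[str, ...]
    peptide_mass: float

    def __post_init__(self) -> None:
        _check_sequence(self.peptide_sequence)
        if self.sp_score < 0:
            raise ValidationError(f"sp_score must be >= 0, got {self.sp_score}")
        if not 0.0 <= self.initial_probability <= 1.0:
            raise ValidationError(
                f"probability must be in [0,1], got {self.initial_probability}"
            )
        if not self.assigned_proteins:
            raise ValidationError("assigned_proteins must be non-empty")
        if self.peptide_mass <= 0:
            raise ValidationError(f"peptide_mass must be > 0, got {self.peptide_mass}")


@dataclass(frozen=True)
class ProteinEntry:
    """One database protein: accession, residue sequence, optional description."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.accession!r} has empty sequence")


@dataclass
class PeptideProteinIndex:
    """Bipartite peptide<->protein maps, kept as exact transposes.

    Peptides that map to no protein at all (orphans) keep an empty entry in
    ``peptide_to_proteins``; they can never enter the inference loop.
    """

    peptide_to_proteins: dict[str, set[str]] = field(default_factory=dict)
    protein_to_peptides: dict[str, set[str]] = field(default_factory=dict)

    def validate_transpose(self) -> None:
        for pep, accs in self.peptide_to_proteins.items():
            for acc in accs:
                if pep not in self.protein_to_peptides.get(acc, ()):
                    raise AssertionError(f"transpose violated at ({pep}, {acc})")
        for acc, peps in self.protein_to_peptides.items():
            for pep in peps:
                if acc not in self.peptide_to_proteins.get(pep, ()):
                    raise AssertionError(f"transpose violated at ({pep}, {acc})")


def canonicalize_peptide(sequence: str, equate_il: bool = False) -> str:
    """Uppercase a peptide sequence, optionally collapsing I and L.

    Isoleucine and leucine are isobaric and indistinguishable by most fragment
    spectra; with ``equate_il`` both are rewritten to L so that such peptides
    share one key.
    """
    seq = sequence.upper()
    return seq.replace("I", "L") if equate_il else seq


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read the canonical tab-separated PSM report.

    Raises :class:`ReportFormatError` naming the first missing required
    column, and :class:`ValidationError` with the 1-based line number for any
    malformed row.  Row order is preserved.
    """
    path = Path(path)
    records: list[PSMRecord] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames or []
        for col in PSM_COLUMNS:
            if col not in header:
                raise ReportFormatError(f"missing required column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                proteins = tuple(
                    p.strip() for p in row["proteins"].split(";") if p.strip()
                )
                records.append(
                    PSMRecord(
                        spectrum_id=row["spectrum_id"],
                        peptide_sequence=row["peptide"].strip().upper(),
                        sp_score=float(row["sp_score"]),
                        initial_probability=float(row["probability"]),
                        assigned_proteins=proteins,
                        peptide_mass=float(row["peptide_mass"]),
                    )
                )
            except (ValidationError, ValueError, TypeError) as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
    return records


_SP_SCORE_KEYS = ("spscore", "sp", "sprime", "spscore_rank")


def read_pepxml_subset(path: str | Path) -> list[PSMRecord]:
    """Read a subset of pepXML: top-ranked hits with a PeptideProphet probability.

    Alternative-protein entries are merged into ``assigned_proteins``.  Hits
    without a probability element are skipped with a logged warning; the
    warning reports the total skipped count semantics per spectrum.
    """
    from pyteomics import pepxml

    records: list[PSMRecord] = []
    skipped = 0
    with pepxml.read(str(path)) as reader:
        for query in reader:
            hits = query.get("search_hit") or []
            if not hits:
                continue
            hit = min(hits, key=lambda h: h.get("hit_rank", 1))
            prob = None
            for result in hit.get("analysis_result", ()):
                pp = result.get("peptideprophet_result")
                if pp is not None and "probability" in pp:
                    prob = float(pp["probability"])
            if prob is None:
                skipped += 1
                logger.warning(
                    "skipping spectrum %s: no PeptideProphet probability",
                    query.get("spectrum"),
                )
                continue
            scores = hit.get("search_score", {})
            sp = None
            for key in scores:
                if key.lower() in _SP_SCORE_KEYS:
                    sp = float(scores[key])
                    break
            if sp is None:
                sp = 0.0
            proteins = tuple(p["protein"] for p in hit.get("proteins", ()))
            mass = float(
                hit.get("calc_neutral_pep_mass")
                or query.get("precursor_neutral_mass")
            )
            records.append(
                PSMRecord(
                    spectrum_id=str(query.get("spectrum")),
                    peptide_sequence=hit["peptide"].upper(),
                    sp_score=sp,
                    initial_probability=prob,
                    assigned_proteins=proteins,
                    peptide_mass=mass,
                )
            )
    if skipped:
        logger.warning("read_pepxml_subset: %d spectrum queries skipped", skipped)
    return records


def read_fasta(path: str | Path) -> list[ProteinEntry]:
    """Read a protein FASTA; sequences are uppercased, '*' terminators stripped."""
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise ValidationError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(record.seq).upper().rstrip("*")
        description = record.description[len(record.id):].strip()
        entries.append(ProteinEntry(accession, sequence, description))
    return entries


def build_index(
    psms: Sequence[PSMRecord],
    proteins: Sequence[ProteinEntry],
    map_by_fasta: bool = False,
) -> PeptideProteinIndex:
    """Construct the two transposed peptide<->protein hash maps.

    With ``map_by_fasta`` a peptide additionally maps to every database
    protein whose sequence contains it as a substring (union with the report
    assignments); otherwise only report assignments are used.  Peptides left
    with no parent are retained as flagged orphans.
    """
    pep_to_prot: dict[str, set[str]] = {}
    for psm in psms:
        parents = pep_to_prot.setdefault(psm.peptide_sequence, set())
        parents.update(psm.assigned_proteins)
    if map_by_fasta:
        for pep, parents in pep_to_prot.items():
            for entry in proteins:
                if pep in entry.sequence:
                    parents.add(entry.accession)
    prot_to_pep: dict[str, set[str]] = {}
    for pep, parents in pep_to_prot.items():
        if not parents:
            logger.warning("orphan peptide %s maps to no protein", pep)
        for acc in parents:
            prot_to_pep.setdefault(acc, set()).add(pep)
    index = PeptideProteinIndex(pep_to_prot, prot_to_pep)
    index.validate_transpose()
    return index


def _fmt(value: float) -> str:
    return format(value, ".9g")


def write_results(proteins: Iterable, peptides: Iterable, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``proteins.tsv`` and ``peptides.tsv`` for final inference states.

    Rows are ordered by descending probability with accession/sequence as the
    tiebreak, so identical runs produce byte-identical files.  Probabilities
    carry 9 significant digits.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    protein_path = out_dir / "proteins.tsv"
    peptide_path = out_dir / "peptides.tsv"

    prot_rows = sorted(proteins, key=lambda s: (-s.q, s.accession))
    with protein_path.open("w", newline="") as handle:
        handle.write("accession\tq\tn_peptides\tn_theoretical\tstatus\tpeptides\n")
        for s in prot_rows:
            handle.write(
                "\t".join(
                    (
                        s.accession,
                        _fmt(s.q),
                        str(s.n_peptides),
                        str(s.n_theoretical),
                        s.status,
                        ";".join(sorted(s.peptides)),
                    )
                )
                + "\n"
            )

    pep_rows = sorted(peptides, key=lambda s: (-s.x, s.peptide_sequence))
    with peptide_path.open("w", newline="") as handle:
        handle.write("peptide\tx\tstatus\tshared\tparents\n")
        for s in pep_rows:
            parents = ";".join(
                f"{acc}:{_fmt(w)}" for acc, w in sorted(s.weights.items())
            )
            handle.write(
                "\t".join(
                    (
                        s.peptide_sequence,
                        _fmt(s.x),
                        "selected" if s.selected else "unselected",
                        "1" if len(s.weights) > 1 else "0",
                        parents,
                    )
                )
                + "\n"
            )
    return protein_path, peptide_path
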