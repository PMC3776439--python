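"""Synthetic proteome + identification-report generator with known ground truth.

Emulates the kind of standard-protein-mix experiment used to validate protein
inference: a database with a known present/absent split, engineered sequence
sharing between proteins (copied tryptic blocks), PSMs whose Sp intensities
scale with parent-protein abundance (a shared peptide's intensity sums the
contributions of all its present parents), and initial peptide probabilities
drawn from well-separated high/low Beta distributions for true/false
identifications.  False peptides are drawn from absent proteins' tryptic
peptide sets, so inference must reject their parents.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import DigestionSettings, peptide_mass, tryptic_peptides
from .report_io import PSMRecord, ProteinEntry, ValidationError

# residues used inside tryptic blocks: no K/R (cleavage sites) — P excluded
# from block starts separately so the proline rule never merges blocks
_BLOCK_RESIDUES = np.array(list("ACDEFGHMNQSTVWY"))
_NONFIRST_RESIDUES = np.array(list("ACDEFGHMNPQSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults: 20 present / 80 absent proteins; 30% of present proteins donate
    one tryptic block to another protein (inducing shared peptides); Sp noise
    is log-normal with sigma 0.3; true/false initial probabilities come from
    Beta(9,1) and Beta(1,9) (medians ~0.93 and ~0.07); one false peptide is
    emitted per five true ones.
    """

    seed: int = 42
    n_present_proteins: int = 20
    n_absent_proteins: int = 80
    protein_length_range: tuple[int, int] = (120, 240)
    shared_block_fraction: float = 0.3
    psm_per_true_peptide_range: tuple[int, int] = (1, 3)
    true_prob_params: tuple[float, float] = (9.0, 1.0)
    false_prob_params: tuple[float, float] = (1.0, 9.0)
    abundance_range: tuple[float, float] = (1.0, 10.0)
    noise_sd: float = 0.3
    false_psm_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("protein_length_range", "psm_per_true_peptide_range",
                     "abundance_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValidationError(f"{name} must be an ordered positive pair")
        if not 0.0 <= self.shared_block_fraction <= 1.0:
            raise ValidationError("shared_block_fraction must be in [0, 1]")
        if not 0.0 <= self.false_psm_rate <= 1.0:
            raise ValidationError("false_psm_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_present_proteins < 1:
            raise ValidationError("need at least one present protein")


@dataclass
class GroundTruth:
    """Truth labels mirroring a standard-mix evaluation.

    ``peptide_labels`` maps each emitted peptide to ``(is_true, is_shared)``;
    "true" means the peptide is a tryptic peptide of at least one present
    protein, "shared" that its sequence occurs in >= 2 database proteins.
    """

    present_proteins: frozenset[str]
    all_proteins: frozenset[str] = frozenset()
    true_peptides: frozenset[str] = frozenset()
    peptide_labels: dict[str, tuple[bool, bool]] = field(default_factory=dict)


def _random_block(rng: np.random.Generator, used: set[str]) -> str:
    """One tryptic block: 6-13 non-K/R residues (no leading P) ending in K or R."""
    while True:
        length = int(rng.integers(6, 14))
        first = str(rng.choice(_BLOCK_RESIDUES))
        rest = "".join(rng.choice(_NONFIRST_RESIDUES, size=length - 1))
        block = first + rest + ("K" if rng.random() < 0.5 else "R")
        if block not in used:
            used.add(block)
            return block


def generate_proteome(config: SyntheticConfig) -> tuple[list[ProteinEntry], GroundTruth]:
    """Random proteins built from distinct tryptic blocks, with engineered sharing.

    For ``shared_block_fraction`` of the present proteins, one block is copied
    over a block of another (present or absent) protein, creating peptides
    with two parents.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    used_blocks: set[str] = set()
    blocks_per_protein: list[list[str]] = []
    accessions: list[str] = []
    n_total = config.n_present_proteins + config.n_absent_proteins
    lo, hi = config.protein_length_range
    for i in range(n_total):
        present = i < config.n_present_proteins
        acc = f"{'PRES' if present else 'ABS'}_{i:04d}"
        target_len = int(rng.integers(lo, hi + 1))
        blocks: list[str] = []
        while sum(len(b) for b in blocks) < target_len:
            blocks.append(_random_block(rng, used_blocks))
        accessions.append(acc)
        blocks_per_protein.append(blocks)

    n_donors = round(config.shared_block_fraction * config.n_present_proteins)
    donors = rng.choice(config.n_present_proteins, size=n_donors, replace=False)
    for donor in sorted(int(d) for d in donors):
        donor_blocks = blocks_per_protein[donor]
        block = donor_blocks[int(rng.integers(len(donor_blocks)))]
        while True:
            target = int(rng.integers(n_total))
            if target != donor:
                break
        target_blocks = blocks_per_protein[target]
        slot = int(rng.integers(len(target_blocks)))
        target_blocks[slot] = block

    proteins = [
        ProteinEntry(acc, "".join(blocks), "synthetic")
        for acc, blocks in zip(accessions, blocks_per_protein)
    ]
    truth = GroundTruth(
        present_proteins=frozenset(accessions[: config.n_present_proteins]),
        all_proteins=frozenset(accessions),
    )
    return proteins, truth


def _parents_of(peptide: str, proteins: Sequence[ProteinEntry]) -> list[str]:
    return sorted(e.accession for e in proteins if peptide in e.sequence)


def simulate_report(
    proteins: Sequence[ProteinEntry],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> tuple[list[PSMRecord], GroundTruth]:
    """Emit PSMs emulating a Sequest + PeptideProphet report.

    Each present protein draws an abundance; every fully tryptic peptide of a
    present protein is observed with 1..k PSMs whose Sp sums the abundances of
    all its present parents times log-normal noise.  False identifications
    are drawn from absent proteins' tryptic peptides at ``false_psm_rate``
    relative to the number of true peptides, with probabilities from the low
    Beta distribution.  Completes and returns the ground-truth labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    digest = DigestionSettings(max_missed_cleavages=0)
    abundance = {
        acc: float(rng.uniform(*config.abundance_range))
        for acc in sorted(truth.present_proteins)
    }
    by_acc = {e.accession: e for e in proteins}

    true_peps: set[str] = set()
    for acc in sorted(truth.present_proteins):
        true_peps |= tryptic_peptides(by_acc[acc].sequence, digest)
    false_pool: set[str] = set()
    for entry in proteins:
        if entry.accession in truth.present_proteins:
            continue
        false_pool |= tryptic_peptides(entry.sequence, digest)
    false_pool -= true_peps

    n_false = round(config.false_psm_rate * len(true_peps))
    false_peps = (
        sorted(
            rng.choice(sorted(false_pool), size=min(n_false, len(false_pool)),
                       replace=False)
        )
        if n_false
        else []
    )

    labels: dict[str, tuple[bool, bool]] = {}
    psms: list[PSMRecord] = []
    spectrum = 0
    k_lo, k_hi = config.psm_per_true_peptide_range
    for pep in sorted(true_peps) + list(false_peps):
        parents = _parents_of(pep, proteins)
        is_true = pep in true_peps
        labels[pep] = (is_true, len(parents) > 1)
        if is_true:
            base = sum(
                abundance[a] for a in parents if a in truth.present_proteins
            )
        else:
            base = float(rng.uniform(*config.abundance_range))
        n_psm = int(rng.integers(k_lo, k_hi + 1))
        mass = peptide_mass(pep)
        a, b = config.true_prob_params if is_true else config.false_prob_params
        for _ in range(n_psm):
            spectrum += 1
            sp = 100.0 * base * float(rng.lognormal(0.0, config.noise_sd))
            prob = float(rng.beta(a, b))
            psms.append(
                PSMRecord(
                    spectrum_id=f"synth.{spectrum:06d}.{spectrum:06d}.2",
                    peptide_sequence=pep,
                    sp_score=sp,
                    initial_probability=prob,
                    assigned_proteins=tuple(parents),
                    peptide_mass=mass,
                )
            )

    completed = GroundTruth(
        present_proteins=truth.present_proteins,
        all_proteins=truth.all_proteins,
        true_peptides=frozenset(true_peps),
        peptide_labels=labels,
    )
    return psms, completed


def emit_fixture(
    proteins: Sequence[ProteinEntry],
    psms: Sequence[PSMRecord],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write ``db.fasta``, ``psms.tsv``, ``truth_proteins.txt``, ``truth_peptides.tsv``."""
    if not truth.present_proteins or not truth.peptide_labels:
        raise ValidationError("refusing to emit a fixture with an empty truth set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "db.fasta",
        "psms": out / "psms.tsv",
        "truth_proteins": out / "truth_proteins.txt",
        "truth_peptides": out / "truth_peptides.tsv",
    }
    with paths["fasta"].open("w") as fh:
        for entry in proteins:
            fh.write(f">{entry.accession} {entry.description}\n")
            for i in range(0, len(entry.sequence), 60):
                fh.write(entry.sequence[i : i + 60] + "\n")
    with paths["psms"].open("w") as fh:
        fh.write("spectrum_id\tpeptide\tsp_score\tprobability\tproteins\tpeptide_mass\n")
        for r in psms:
            fh.write(
                f"{r.spectrum_id}\t{r.peptide_sequence}\t{r.sp_score:.6f}\t"
                f"{r.initial_probability:.6f}\t{';'.join(r.assigned_proteins)}\t"
                f"{r.peptide_mass:.6f}\n"
            )
    with paths["truth_proteins"].open("w") as fh:
        for acc in sorted(truth.all_proteins):
            label = "present" if acc in truth.present_proteins else "absent"
            fh.write(f"{acc}\t{label}\n")
    with paths["truth_peptides"].open("w") as fh:
        fh.write("peptide\tlabel\tshared\n")
        for pep in sorted(truth.peptide_labels):
            is_true, is_shared = truth.peptide_labels[pep]
            fh.write(
                f"{pep}\t{'true' if is_true else 'false'}\t{int(is_shared)}\n"
            )
    return paths


def load_truth(
    truth_proteins: str | Path, truth_peptides: str | Path | None = None
) -> GroundTruth:
    """Read the truth files written by :func:`emit_fixture`."""
    present: set[str] = set()
    universe: set[str] = set()
    for line in Path(truth_proteins).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        acc = parts[0]
        universe.add(acc)
        if len(parts) < 2 or parts[1] == "present":
            present.add(acc)
    labels: dict[str, tuple[bool, bool]] = {}
    if truth_peptides is not None:
        lines = Path(truth_peptides).read_text().splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            pep, label, shared = line.split("\t")
            labels[pep] = (label == "true", shared == "1")
    return GroundTruth(
        present_proteins=frozenset(present),
        all_proteins=frozenset(universe),
        true_peptides=frozenset(p for p, (t, _) in labels.items() if t),
        peptide_labels=labels,
    )
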