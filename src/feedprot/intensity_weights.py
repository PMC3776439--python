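"""MS/MS intensity-based assignment of shared peptides to parent proteins.

A peptide observed in several database proteins cannot be attributed to one
parent from sequence alone.  The strategy here uses fragment-intensity
closeness: the intensity of a peptide is the sum of its (dataset-normalized)
Sequest Sp scores across matched spectra, and a shared peptide is assigned
preferentially to the parent protein whose *sibling* peptides (other selected
peptides of that protein) have an average intensity close to the peptide's
own.  The per-parent assignment probabilities w_ik sum to one over the active
parents; a peptide unique to one active protein gets weight exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .report_io import PSMRecord, PeptideProteinIndex, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeptideIntensity:
    """Summed normalized Sp intensity I_p of one peptide over its N_s spectra."""

    peptide_sequence: str
    intensity: float
    n_spectra: int


@dataclass(frozen=True)
class WeightAssignment:
    """Per-parent assignment probabilities w_ik of one peptide."""

    peptide_sequence: str
    weights: Mapping[str, float]
    shared: bool


def normalize_sp(psms: Sequence[PSMRecord]) -> list[float]:
    """Divide every Sp score by the dataset-wide maximum; results in [0, 1]."""
    if not psms:
        raise ValidationError("cannot normalize an empty PSM list")
    max_sp = max(p.sp_score for p in psms)
    if max_sp <= 0:
        raise ValidationError("degenerate dataset: all Sp scores are zero")
    return [p.sp_score / max_sp for p in psms]


def peptide_intensity(
    peptide: str, normalized_sp: Sequence[float]
) -> PeptideIntensity:
    """I_p: the sum of the peptide's normalized Sp values over its spectra."""
    if not normalized_sp:
        raise ValidationError(f"peptide {peptide} has no matched PSMs")
    return PeptideIntensity(peptide, float(sum(normalized_sp)), len(normalized_sp))


def intensity_table(psms: Sequence[PSMRecord]) -> dict[str, PeptideIntensity]:
    """Per-peptide intensities for a whole report (normalized once, summed).

    Computed once from the full report; only the weights and peptide counts
    are iteration-dependent downstream.
    """
    normalized = normalize_sp(psms)
    grouped: dict[str, list[float]] = {}
    for psm, sp in zip(psms, normalized):
        grouped.setdefault(psm.peptide_sequence, []).append(sp)
    return {
        pep: peptide_intensity(pep, values) for pep, values in sorted(grouped.items())
    }


def sibling_intensity(
    peptide: str,
    protein: str,
    selected_peptides: Iterable[str],
    intensities: Mapping[str, PeptideIntensity],
    index: PeptideProteinIndex,
) -> float | None:
    """Average intensity I_b of the protein's other selected peptides.

    Siblings are all currently selected peptides of the protein except the
    query peptide itself (shared siblings included).  Returns ``None`` when
    the protein has no siblings to average.
    """
    members = index.protein_to_peptides.get(protein, set())
    # sorted so the float summation order is process-independent
    siblings = sorted(
        p for p in members if p != peptide and p in set(selected_peptides)
    )
    if not siblings:
        return None
    return sum(intensities[p].intensity for p in siblings) / len(siblings)


def shared_weights(
    peptide: str,
    intensity: float,
    sibling_means: Mapping[str, float | None],
) -> WeightAssignment:
    """Assignment probabilities for a peptide shared by >= 2 active parents.

    For each parent k the normalized distance to its own sibling average is
    d_k = |I_p - I_b(k)| / I_p (d_k = 1 when the parent has no siblings).  The
    raw weight of parent k is the mean of d_j over the *other* parents — the
    farther the peptide lies from the competitors' siblings, the more of it
    parent k claims — and raw weights are normalized to sum to one.  With two
    parents this is exactly the pairwise proportion rule.  Degenerate cases
    (I_p = 0, or all distances zero) fall back to uniform weights.
    """
    parents = sorted(sibling_means)
    if len(parents) < 2:
        raise ValidationError(
            f"shared_weights requires >= 2 parents, got {len(parents)}"
        )
    if intensity <= 0:
        uniform = 1.0 / len(parents)
        return WeightAssignment(peptide, {k: uniform for k in parents}, True)
    dist = {}
    for k in parents:
        ib = sibling_means[k]
        dist[k] = 1.0 if ib is None else abs(intensity - ib) / intensity
    raw = {
        k: sum(dist[j] for j in parents if j != k) / (len(parents) - 1)
        for k in parents
    }
    total = sum(raw.values())
    if total <= 0:
        uniform = 1.0 / len(parents)
        return WeightAssignment(peptide, {k: uniform for k in parents}, True)
    return WeightAssignment(peptide, {k: raw[k] / total for k in parents}, True)


def assign_weights(
    selected_peptides: Iterable[str],
    active_proteins: Iterable[str],
    index: PeptideProteinIndex,
    intensities: Mapping[str, PeptideIntensity],
) -> dict[str, WeightAssignment]:
    """w_ik for every selected peptide over the currently active proteins.

    Unique peptides (one active parent) get weight 1; shared peptides are
    apportioned by :func:`shared_weights`.  Recomputed from scratch each
    iteration — the active set and selection change as the loop proceeds.
    Peptides with zero active parents are excluded and logged.
    """
    selected = set(selected_peptides)
    active = set(active_proteins)
    table: dict[str, WeightAssignment] = {}
    for pep in sorted(selected):
        parents = sorted(index.peptide_to_proteins.get(pep, set()) & active)
        if not parents:
            logger.warning("peptide %s has no active parent; excluded", pep)
            continue
        if len(parents) == 1:
            table[pep] = WeightAssignment(pep, {parents[0]: 1.0}, False)
            continue
        means = {
            k: sibling_intensity(pep, k, selected, intensities, index)
            for k in parents
        }
        table[pep] = shared_weights(pep, intensities[pep].intensity, means)
    return table
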