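"""The iterative feedback loop that co-estimates protein and peptide probabilities.

Starting from search-engine peptide probabilities, each iteration
(1) selects high-confidence peptides, (2) collects their parent proteins as
the putative list and scores each protein as

    q_k = [1 - prod_i (1 - x_i * w_ik * q_k_prev)] ** (-ln(n_k / N_k)),

where x_i are peptide probabilities, w_ik the shared-peptide assignment
probabilities, n_k the protein's selected peptide count and N_k its
theoretical peptide count, then (3) replenishes the peptide list with
previously low-confidence peptides contained in high-confidence proteins and
recomputes every selected peptide's probability as x_i = sum_k w_ik * q_k.
All protein probabilities start at 1 (every protein with identified
constituent peptides is a priori equally plausible).

Absent proteins that keep re-entering the putative list only through peptides
shared with confidently present proteins show an in->out->in membership
pattern; such proteins are permanently eliminated, which is what lets the
peptide and protein lists reach a steady state.  Iteration stops when both
lists are unchanged and no protein probability moves more than a tolerance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .digestion import DigestionSettings, count_theoretical_peptides, infer_mass_window
from .intensity_weights import WeightAssignment, assign_weights, intensity_table
from .report_io import (
    PSMRecord,
    PeptideProteinIndex,
    ProteinEntry,
    ValidationError,
    build_index,
    canonicalize_peptide,
)

logger = logging.getLogger(__name__)


@dataclass
class ProteinState:
    """Lifecycle of one protein across the iteration.

    ``status`` is ``active`` while on the putative list, ``dropped`` after
    falling off it, and ``eliminated`` (terminal) once the in->out->in
    re-entry pattern has been seen.  ``membership_history`` records one
    "in"/"out" mark per iteration from first entry onward.
    """

    accession: str
    q: float = 1.0
    n_peptides: int = 0
    n_theoretical: int = 1
    status: str = "active"
    membership_history: list[str] = field(default_factory=list)
    peptides: tuple[str, ...] = ()


@dataclass
class PeptideState:
    """One distinct peptide sequence and its evolving probability x."""

    peptide_sequence: str
    x: float
    initial_x: float
    selected: bool = False
    parents: frozenset[str] = frozenset()
    weights: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds and stopping rules for the feedback loop."""

    peptide_threshold: float = 0.95
    protein_threshold: float = 0.95
    q_tolerance: float = 1e-6
    max_iterations: int = 100
    elimination_cycles: int = 1
    log_base: float | None = None  # None = natural log in the q exponent
    map_by_fasta: bool = False
    equate_il: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.peptide_threshold <= 1.0:
            raise ValidationError("peptide_threshold must be in (0, 1]")
        if not 0.0 < self.protein_threshold <= 1.0:
            raise ValidationError("protein_threshold must be in (0, 1]")
        if self.q_tolerance <= 0:
            raise ValidationError("q_tolerance must be positive")
        if self.elimination_cycles < 1:
            raise ValidationError("elimination_cycles must be >= 1")


@dataclass(frozen=True)
class IterationSnapshot:
    """Active proteins, their q values, and the selected peptide set at one iteration."""

    iteration: int
    active_proteins: frozenset[str]
    q_vector: Mapping[str, float]
    selected_peptides: frozenset[str]


@dataclass
class InferenceResult:
    proteins: dict[str, ProteinState]
    peptides: dict[str, PeptideState]
    snapshots: list[IterationSnapshot]
    converged: bool
    iterations: int
    iteration_log: list[dict]
    weight_history: list[dict[str, WeightAssignment]]


def protein_probability(
    x_values: Sequence[float],
    weights: Sequence[float],
    q_prev: float,
    n_k: int,
    N_k: int,
    log_base: float | None = None,
) -> float:
    """Protein probability q from its selected peptides' evidence.

    Conventions: n_k = 0 gives q = 0 (no evidence); n_k = N_k gives exponent
    0, so q = 1 when the bracket is positive and q = 0 when it is zero (0**0
    resolved to 0 — certainty must not come from no positive evidence).  The
    result is clamped to [0, 1].
    """
    if len(x_values) != len(weights) or len(x_values) != n_k:
        raise ValidationError("x_values, weights and n_k must agree in length")
    if n_k == 0:
        return 0.0
    if N_k < max(n_k, 1):
        raise ValidationError(f"N_k ({N_k}) must be >= max(n_k, 1) ({max(n_k, 1)})")
    prod = 1.0
    for x, w in zip(x_values, weights):
        prod *= 1.0 - x * w * q_prev
    bracket = min(max(1.0 - prod, 0.0), 1.0)
    if n_k == N_k:
        return 1.0 if bracket > 0.0 else 0.0
    exponent = -math.log(n_k / N_k)
    if log_base is not None:
        exponent /= math.log(log_base)
    if bracket == 0.0:
        return 0.0
    return min(max(bracket**exponent, 0.0), 1.0)


def select_peptides(
    peptides: Mapping[str, PeptideState],
    threshold: float,
    eliminated: frozenset[str] | set[str] = frozenset(),
) -> set[str]:
    """Peptides with x >= threshold and at least one non-eliminated parent."""
    return {
        seq
        for seq, state in peptides.items()
        if state.x >= threshold and (state.parents - set(eliminated))
    }


def putative_proteins(
    selected: set[str],
    index: PeptideProteinIndex,
    eliminated: frozenset[str] | set[str] = frozenset(),
) -> set[str]:
    """Union of the selected peptides' parents, minus eliminated proteins."""
    active: set[str] = set()
    for pep in selected:
        active |= index.peptide_to_proteins.get(pep, set())
    return active - set(eliminated)


def replenish_peptides(
    high_confidence: set[str],
    peptides: Mapping[str, PeptideState],
    selected: set[str],
    index: PeptideProteinIndex,
) -> set[str]:
    """Add unselected peptides contained in a high-confidence protein.

    This is the feedback step: confidently inferred proteins pull their
    low-probability constituent peptides back into the selected list
    regardless of current x.  Previously selected peptides are retained.
    """
    augmented = set(selected)
    for seq, state in peptides.items():
        if seq in augmented:
            continue
        if index.peptide_to_proteins.get(seq, set()) & high_confidence:
            augmented.add(seq)
    return augmented


def recompute_peptide_probabilities(
    selected: set[str],
    weights: Mapping[str, WeightAssignment],
    q_vector: Mapping[str, float],
) -> tuple[dict[str, float], list[str]]:
    """x_i = sum_k w_ik q_k over active parents; returns (new x, dropped peptides)."""
    new_x: dict[str, float] = {}
    dropped: list[str] = []
    for pep in sorted(selected):
        wa = weights.get(pep)
        if wa is None:
            dropped.append(pep)
            logger.warning("peptide %s has no active parents; dropped", pep)
            continue
        x = sum(w * q_vector[acc] for acc, w in wa.weights.items())
        new_x[pep] = min(max(x, 0.0), 1.0)
    return new_x, dropped


def apply_elimination(
    protein_states: Mapping[str, ProteinState], config: InferenceConfig
) -> list[str]:
    """Permanently eliminate proteins showing the in->out->in re-entry pattern.

    A re-entry is an "in" mark immediately after an "out"; histories always
    start with "in", so ``elimination_cycles`` re-entries means the protein
    has completed that many full in->out->in cycles.
    """
    newly: list[str] = []
    for acc in sorted(protein_states):
        state = protein_states[acc]
        if state.status == "eliminated":
            continue
        hist = state.membership_history
        reentries = sum(
            1
            for t in range(1, len(hist))
            if hist[t - 1] == "out" and hist[t] == "in"
        )
        if reentries >= config.elimination_cycles:
            state.status = "eliminated"
            newly.append(acc)
    return newly


def check_convergence(
    previous: IterationSnapshot | None,
    current: IterationSnapshot,
    config: InferenceConfig,
) -> bool:
    """Converged iff both lists are unchanged and max |Δq| < q_tolerance."""
    if previous is None:
        return False
    if previous.active_proteins != current.active_proteins:
        return False
    if previous.selected_peptides != current.selected_peptides:
        return False
    max_dq = max(
        (
            abs(current.q_vector[acc] - previous.q_vector[acc])
            for acc in current.active_proteins
        ),
        default=0.0,
    )
    return max_dq < config.q_tolerance


def _initial_peptide_states(
    psms: Sequence[PSMRecord],
    index: PeptideProteinIndex,
) -> dict[str, PeptideState]:
    by_pep: dict[str, float] = {}
    for psm in psms:
        prev = by_pep.get(psm.peptide_sequence, 0.0)
        # peptide-level probability = max over the peptide's PSMs
        by_pep[psm.peptide_sequence] = max(prev, psm.initial_probability)
    return {
        seq: PeptideState(
            peptide_sequence=seq,
            x=prob,
            initial_x=prob,
            parents=frozenset(index.peptide_to_proteins.get(seq, set())),
        )
        for seq, prob in sorted(by_pep.items())
    }


def run_inference(
    psms: Sequence[PSMRecord],
    proteins: Sequence[ProteinEntry],
    config: InferenceConfig | None = None,
    digestion: DigestionSettings | None = None,
    theoretical_counts: Mapping[str, int] | None = None,
) -> InferenceResult:
    """Run the full feedback loop to convergence (or ``max_iterations``).

    ``theoretical_counts`` overrides the FASTA-derived N_k per accession
    (useful for testing and for accessions absent from the database; missing
    entries fall back to digesting the database sequence, and finally to
    ``max(n_k, 1)`` so the exponent stays well defined).
    """
    config = config or InferenceConfig()
    if config.equate_il:
        psms = [
            replace(p, peptide_sequence=canonicalize_peptide(p.peptide_sequence, True))
            for p in psms
        ]
    index = build_index(psms, proteins, map_by_fasta=config.map_by_fasta)
    if psms:
        intensities = intensity_table(psms)
    else:
        intensities = {}
    peptide_states = _initial_peptide_states(psms, index)

    if digestion is None:
        digestion = DigestionSettings()
    if digestion.mass_min is None and digestion.mass_max is None and psms:
        lo, hi = infer_mass_window(psms)
        if lo < hi:
            digestion = replace(digestion, mass_min=lo, mass_max=hi)

    sequences = {entry.accession: entry.sequence for entry in proteins}
    n_theo_cache: dict[str, int | None] = dict(theoretical_counts or {})

    def n_theoretical(acc: str, n_k: int) -> int:
        if acc not in n_theo_cache:
            seq = sequences.get(acc)
            n_theo_cache[acc] = (
                count_theoretical_peptides(seq, digestion) if seq else None
            )
        cached = n_theo_cache[acc]
        base = cached if cached is not None else 0
        return max(base, n_k, 1)  # clamp keeps -log(n_k/N_k) >= 0

    protein_states: dict[str, ProteinState] = {}
    eliminated: set[str] = set()
    prev_active: set[str] = set()
    snapshots: list[IterationSnapshot] = []
    iteration_log: list[dict] = []
    weight_history: list[dict[str, WeightAssignment]] = []
    prev_snapshot: IterationSnapshot | None = IterationSnapshot(
        0, frozenset(), {}, frozenset()
    )
    converged = False
    iteration = 0

    for iteration in range(1, config.max_iterations + 1):
        # (1) high-confidence peptide selection
        selected = select_peptides(peptide_states, config.peptide_threshold, eliminated)
        # (2) putative protein list
        active = putative_proteins(selected, index, eliminated)

        # weights over the pre-replenishment selection feed the q update
        weights_in = assign_weights(selected, active, index, intensities)

        q_vector: dict[str, float] = {}
        for acc in sorted(active):
            members = sorted(index.protein_to_peptides.get(acc, set()) & selected)
            n_k = len(members)
            N_k = n_theoretical(acc, n_k)
            state = protein_states.get(acc)
            if state is None:
                state = ProteinState(accession=acc)
                protein_states[acc] = state
            q_prev = state.q if acc in prev_active else 1.0
            x_vals = [peptide_states[p].x for p in members]
            w_vals = [weights_in[p].weights[acc] for p in members]
            q = protein_probability(
                x_vals, w_vals, q_prev, n_k, N_k, log_base=config.log_base
            )
            state.q = q
            state.n_peptides = n_k
            state.n_theoretical = N_k
            state.status = "active"
            state.peptides = tuple(members)
            q_vector[acc] = q

        # membership bookkeeping (only proteins seen at least once have history)
        for acc, state in protein_states.items():
            if state.status == "eliminated":
                continue
            if acc in active:
                state.membership_history.append("in")
            else:
                state.membership_history.append("out")
                if state.status == "active":
                    state.status = "dropped"

        # (3) feedback: replenish from high-confidence proteins, recompute x
        high_conf = {acc for acc, q in q_vector.items() if q >= config.protein_threshold}
        selected = replenish_peptides(high_conf, peptide_states, selected, index)
        weights_out = assign_weights(selected, active, index, intensities)
        new_x, dropped = recompute_peptide_probabilities(selected, weights_out, q_vector)
        selected -= set(dropped)

        # elimination of in->out->in proteins; survivors' weights renormalize
        newly_eliminated = apply_elimination(protein_states, config)
        if newly_eliminated:
            eliminated.update(newly_eliminated)
            active -= set(newly_eliminated)
            for acc in newly_eliminated:
                q_vector.pop(acc, None)
            weights_out = assign_weights(selected, active, index, intensities)
            new_x, dropped = recompute_peptide_probabilities(
                selected, weights_out, q_vector
            )
            selected -= set(dropped)

        for pep, x in new_x.items():
            peptide_states[pep].x = x
        for pep, state in peptide_states.items():
            state.selected = pep in selected
            state.weights = dict(weights_out[pep].weights) if pep in weights_out else {}

        snapshot = IterationSnapshot(
            iteration, frozenset(active), dict(q_vector), frozenset(selected)
        )
        max_dq = max(
            (
                abs(snapshot.q_vector[a] - prev_snapshot.q_vector[a])
                for a in snapshot.active_proteins & prev_snapshot.active_proteins
            ),
            default=0.0,
        )
        iteration_log.append(
            {
                "iteration": iteration,
                "n_active": len(active),
                "n_selected": len(selected),
                "max_dq": max_dq,
                "eliminated": list(newly_eliminated),
            }
        )
        logger.info(
            "iteration %d: %d active proteins, %d selected peptides, "
            "max|dq|=%.3g, %d eliminated",
            iteration,
            len(active),
            len(selected),
            max_dq,
            len(newly_eliminated),
        )
        snapshots.append(snapshot)
        weight_history.append(weights_out)
        converged = check_convergence(prev_snapshot, snapshot, config)
        prev_snapshot = snapshot
        prev_active = set(active)
        if converged:
            break

    if not converged:
        logger.warning("inference stopped at max_iterations=%d without converging",
                       config.max_iterations)

    # peptides with every parent eliminated revert to their report probability
    for pep, state in peptide_states.items():
        if state.parents and not (state.parents - eliminated):
            state.x = state.initial_x
            state.selected = False
            state.weights = {}

    return InferenceResult(
        proteins=protein_states,
        peptides=peptide_states,
        snapshots=snapshots,
        converged=converged,
        iterations=iteration,
        iteration_log=iteration_log,
        weight_history=weight_history,
    )
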