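# Methods

## Model

`feedprot` treats protein inference and peptide identification as one
fixed-point problem on the bipartite peptide–protein graph.  Three coupled
quantities are iterated:

- **Protein probability.**  For protein *Q_k* with `n_k` currently selected
  peptides, `N_k` theoretical peptides and previous probability `q'`,

      q_k = [1 − Π_i (1 − x_i w_ik q')] ^ (−ln(n_k / N_k)).

  The bracket is the probability that at least one of the protein's selected
  peptides is a correct identification that truly originates from it; the
  exponent `−ln(n_k/N_k) ≥ 0` penalizes proteins that yield only a small
  fraction of their observable peptides, so long proteins cannot be carried
  by one or two matches.  The events "peptide correctly identified",
  "peptide originates from this protein" and "protein present" are treated
  as independent.

- **Shared-peptide weights.**  `w_ik` is the probability that peptide *P_i*
  originates from parent *Q_k*.  The peptide's intensity `I_p` is the sum of
  its dataset-max-normalized Sequest Sp scores over all matched spectra
  (computed once from the full report).  For each active parent, the sibling
  average `I_b(k)` is the mean intensity of the parent's *other* selected
  peptides; averaging over siblings damps peptide-detectability differences.
  With normalized distances `d_k = |I_p − I_b(k)| / I_p`, the raw weight of
  parent *k* is the mean of `d_j` over the competing parents, normalized to
  sum to one — the parent whose own siblings lie closest to the peptide
  receives the largest weight.  For two parents this reduces exactly to the
  pairwise proportion rule; the mean-over-competitors form is the package's
  generalization to ≥ 3 parents, chosen because it is order-invariant and
  collapses to the two-parent rule.  A peptide unique among active parents
  has weight exactly 1.

- **Peptide probability.**  After each protein update, every selected
  peptide is re-scored as `x_i = Σ_k w_ik q_k` over its active parents.

## The loop

Initialization: every protein starts at `q = 1` (any protein with
identified constituent peptides is a priori equally plausible); peptide
probabilities start at the search-engine posteriors, aggregated per distinct
sequence as the maximum over that peptide's PSMs.

Each iteration: select peptides with `x ≥` the peptide threshold (default
0.95) that retain a non-eliminated parent; collect their parents as the
putative list; recompute `n_k` and weights from the current selection;
update every `q_k`; replenish the selection with unselected peptides
contained in proteins with `q ≥` the protein threshold (default 0.95);
recompute weights over the augmented selection and update every selected
`x_i`.  Replenished peptides are re-evaluated against the selection
threshold at every subsequent iteration — feedback admits them once, the
weighted-parent re-scoring decides whether they stay.

**Elimination.**  A membership history ("in"/"out" per iteration) is kept
for every protein from its first appearance.  A protein whose history shows
a completed in → out → in cycle (a re-entry after dropping off the putative
list) is eliminated permanently: its unique peptides leave the selection and
the weights of its shared peptides renormalize among the survivors.  One
cycle suffices by default (`elimination_cycles` is configurable); this is
the mechanism that stops absent proteins from oscillating in via peptides
shared with present proteins, and it is what makes the peptide and protein
lists reach a steady state.  Peptides whose every parent has been eliminated
are reported unselected with their original report probability, keeping the
false-positive linkage auditable.

**Convergence.**  The loop stops when the active protein set and the
selected peptide set are unchanged and `max_k |Δq_k| < 1e−6` (at most 100
iterations, with a warning and a non-converged flag otherwise).  At a fixed
selection, the q-update is monotone in `q'` on [0, 1], so the per-protein
sequence started at 1 is decreasing and bounded — convergence in practice is
geometric, and the synthetic fixtures settle in well under ten iterations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `peptide_threshold` | 0.95 | high-confidence peptide selection cut |
| `protein_threshold` | 0.95 | high-confidence protein cut for replenishment |
| `q_tolerance` | 1e−6 | convergence tolerance on protein probabilities |
| `max_iterations` | 100 | iteration cap |
| `elimination_cycles` | 1 | in→out→in cycles before permanent elimination |
| `digest.max_missed` | 2 | missed cleavages allowed in N_k |
| `digest.mass_min/max` | from report | theoretical-peptide mass window (Da) |
| `digest.mass_kind` | monoisotopic | residue mass table for the window filter |
| `digest.proline_rule` | on | no cleavage of K/R–P bonds |

## Numerical and design choices

- **Logarithm base.**  The exponent uses the natural logarithm; the base
  only rescales the exponent and is overridable (`log_base`).
- **Degenerate exponents.**  `n_k = 0` gives `q = 0`.  `n_k = N_k` gives
  exponent 0: `q = 1` when the bracket is positive, and `q = 0` when it is
  zero — `0^0` is resolved to 0 so that certainty can never arise from no
  positive evidence.  If a database-derived `N_k` is smaller than `n_k`
  (semi-tryptic identifications) or unavailable, it is clamped to
  `max(N_k, n_k, 1)` so the exponent stays non-negative.
- **Weight degeneracies.**  A parent with no siblings gets distance 1 (no
  corroboration pushes weight toward corroborated parents); if `I_p = 0` or
  all distances vanish, weights fall back to uniform.
- **Proline rule.**  The digestion rule is the plain `[KR]` not-before-`P`
  regex rather than the full Expasy trypsin exception list, matching common
  search-engine practice and keeping the brute-force oracle unambiguous.
- **Determinism.**  All iteration orders are sorted (accessions, peptide
  sequences), including float summation orders, so identical inputs give
  byte-identical outputs across processes regardless of hash randomization.
- **I/L ambiguity.**  Peptides are keyed by exact sequence; an `equate_il`
  switch collapses I to L for pipelines where the distinction is spurious.
- **Peptide→protein mapping.**  By default the search engine's protein
  assignments define the graph; `map_by_fasta` adds substring matching
  against the database (union), for reports that list only one parent per
  hit.

## Synthetic data

The generator emulates a standard-protein-mix benchmark.  Proteins are
concatenations of distinct random tryptic blocks (6–13 non-K/R residues plus
a terminal K/R; no block-initial proline), 120–240 residues, split into 20
present and 80 absent by default.  For 30 % of present proteins one block is
copied over a block of another random protein, engineering shared peptides —
including present/absent sharing, which is what exercises the elimination
rule.  Each present protein draws an abundance uniform on [1, 10]; every
fully tryptic peptide of a present protein is observed with 1–3 PSMs whose
Sp is 100 × (sum of its present parents' abundances) × log-normal(σ = 0.3)
noise, so a shared peptide's intensity adds its parents' contributions.
False identifications are sampled from absent proteins' tryptic peptides at
one per five true peptides.  Initial probabilities come from Beta(9, 1) for
true and Beta(1, 9) for false PSMs — medians ≈ 0.93 vs ≈ 0.07, the
well-separated bimodal shape a PeptideProphet mixture produces on a clean
mix.

What the generator does *not* model: spectrum-level noise, retention time,
charge states, peptide detectability differences beyond log-normal intensity
spread, semi-tryptic or modified peptides, and homology-scale sequence
similarity (sharing is exact block copying).  Tests passing on these
fixtures therefore demonstrate correctness of the algorithm and its
steady-state behaviour, not performance on real instrument data.

## Problem sizes

The test suite and the acceptance script run the default 100-protein /
~900-PSM synthetic study (fractions of a second per inference run), 100
randomized small instances against an independently coded straight-line
re-implementation of the loop, 200 randomized digestion oracles, and
1000-case weight-contract audits.  These sizes were chosen so the whole
suite completes in seconds while still covering every branch of the model.

## Known limitations

- No protein grouping: indistinguishable proteins (identical peptide sets)
  are scored independently and can both be reported.
- No FDR machinery or decoy handling; evaluation requires ground truth.
- The pepXML reader is a deliberate subset (spectrum queries, top-ranked
  hits, alternative proteins, Sp score, PeptideProphet probability).
- Peptide detectability is only damped by sibling averaging, not modeled.
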