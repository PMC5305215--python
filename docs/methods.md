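# Methods

## Quantification model

The pipeline starts at protein-level SILAC quantification tables (one row
per protein: accession, light/heavy ratio, L/H count). Spectral search,
peptide-to-protein roll-up, FDR filtering, and SILAC channel correction are
upstream concerns of the search engine and are out of scope; rows with an
L/H count of zero or a missing ratio are dropped on read because they carry
no usable quantification.

For a replicate, a protein's import index is `+NTR/Ctl =
(L/H_+NTR)/(L/H_Ctl)`. Both measurements are required; proteins quantified
in only one of the paired runs are discarded rather than imputed. The index
is analysed as `X = log2(+NTR/Ctl)` and standardized replicate-wide,
`Z = (X − μ)/σ`, over **all** paired proteins of the replicate — the
standardization absorbs global run-to-run shifts (e.g. differing receptor
activity or extract composition between replicates), which is its purpose.

Conventions fixed for reproducibility where the procedure is otherwise
underdetermined:

- **Standard deviation**: sample (n−1). With 10³ proteins per replicate the
  difference from the population convention is ~0.05% and cannot change any
  ranking, but it is fixed and tested (mean 0 / sd 1 within 1e-9).
- **Degenerate input**: fewer than two paired proteins, or zero spread, is
  an error, not a silent NaN.
- **No winsorization or trimming** before standardization.

## Replicate aggregation and cargo calls

Per protein, the 2–3 replicate Z-scores are reduced by order statistics:
the second-largest ("2nd-Z", the lower of two or middle of three) keeps
proteins that scored well at least twice; the minimum of three ("3rd-Z")
requires consistency in every replicate. Proteins with a single value are
excluded entirely. The 3rd-Z population is by construction a subset of the
2nd-Z population.

Cargo sets are called by rank percentile with member count
`floor(N·pct/100)` — the floor rule reproduces the published set sizes
247/1649 (15%), 309/2060 (15%), 49/1235 (4%), and 66/1671 (4%). Two
published 15% set sizes are one *below* the floor value (302 vs 303 of
2021; 303 vs 304 of 2027); the cause is unknowable from the text (boundary
ties or manual curation), so the floor count is the default and an explicit
`count=` override exists for reproducing externally fixed sizes.

Ranking ties are broken deterministically: larger sum of the remaining
order statistics first, then lexicographic accession. The choice matters
only when tied proteins straddle a percentile boundary; determinism makes
outputs byte-stable.

## Cutoff calibration

At each percentile `i` (default 1% increments), the top slice is scored as
`rate(i) = p(i)/[p(i)+n(i)]` and `recall(i) = p(i)/P`. Two negative-example
definitions are supported, because no gold-standard non-cargo set exists:
treating every unreported protein as negative (rate = a lower bound on
precision), or treating only unreported proteins with non-nuclear
localization as negative and excluding the rest from the evaluation
universe. Slices are taken on the full ranking first and the exclusion
applied inside the slice; recall always uses the full positive count.

Enrichment significance is the one-sided Fisher exact test — the upper tail
`P(X ≥ k)` of Hypergeometric(N, K, n) — summed in log-space via log-gamma
and logsumexp so that p-values of order 1e-22 are exact to machine
precision. One-sidedness reproduces the published p-values exactly (e.g.
the closed-form two-positive case `C(18,2)/C(1591,2) = 1.21e-4`), so it is
taken as the established convention for this analysis. No continuity
correction, no mid-p, and no multiple-testing correction across cutoffs:
the sweep is descriptive calibration, not inference.

## Motif scanning

Patterns are declarative element lists (residue classes, bounded gaps,
literals, and fixed-width enrichment windows) compiled to regular
expressions; all match start positions are reported via lookahead. The
shipped PY-NLS defaults encode the canonical consensus: a C-terminal
R/K/H–X(2–5)–P–Y element preceded within a 0–30 residue linker by either a
hydrophobic N-terminal element Φ–[GAS]–Φ–Φ (Φ ∈ {W,F,Y,L,I,V,M}) or a basic
element (≥4 K/R within a 6-residue window). These are canonical consensus
definitions, not transcriptions of any particular figure graphic; every
class and bound is overridable in config. Structural disorder, a known
contextual requisite of functional PY-NLSs, is deliberately not evaluated —
the scan is sequence-only, so motif "positives" are sequence matches, not
validated signals. Motif density along a ranking is the percentage of
motif-positive proteins in a 50-rank sliding window (stride 1).

## Cargo-profile comparison

Called cargo sets are compared by exact set algebra (pairwise shared
counts, per-receptor unique cargoes, mean pairwise sharing) and as a binary
receptors × cargo-universe membership matrix. Rows are clustered
agglomeratively with Ward linkage on Euclidean distances, implemented as
the Lance–Williams recurrence. Two dialects exist because R's `hclust`
historically offered both: the default applies the recurrence to squared
distances and reports heights on the distance scale (`ward.D2`, identical
to scipy's `linkage(..., "ward")`, which is the cross-check oracle in the
tests); the alternative applies it to unsquared distances (`ward.D`). The
agglomeration tie-break is the lexicographically smallest cluster-id pair
among minimal-distance pairs. Dendrograms export to Newick with branch
lengths equal to merge-height differences.

## Synthetic data generator

The generator emulates the protein-level tables of a reconstituted-import
screen. Per protein: abundance `a ~ LogNormal(0, 1)` (dimensionless,
median 1) and a baseline log2 L/H ~ Normal(0, 0.5). Per run: independent
noise Normal(0, `noise_log2` = 0.6) on the log2 scale, an optional global
per-run shift (off by default; switching it on exercises what the
within-replicate Z-normalization is for), counts `lh_count ~
Poisson(4 + 5a)`, and dropout with probability `0.08/(1+a)`. A protein is
absent from a run when its count draws zero or it drops out, which yields
the missing-counterpart structure the pairing rule discards. The count and
dropout defaults were calibrated so that about four proteins are quantified
in all three replicate pairs for every one quantified in exactly two,
matching the replicate structure reported for real screens of this kind
(receptor-wise ratios of roughly 2.5–4.6); the noise sd is a testability
choice, as no empirical value is published for X.

Planted cargoes (default 8% of proteins per receptor, overlapping between
designated receptor pairs via `sharing_design`) receive an import effect
δ ~ Normal(1.5, 0.5) log2 units truncated at ≥ 0.3, added in the +NTR
condition only. "Reported" labels are drawn from planted cargoes only
(default 10%), so evaluation positives are true by construction and the
expected behavior of the Fisher sweep is analytically predictable; planted
cargoes are labeled nuclear, and non-cargoes are non-nuclear with
probability 0.15, otherwise split evenly between nuclear and undetermined.
One control run per replicate is shared by all receptors (real screens
shared controls between receptor pairs; one shared control is the
simplification).

What the generator does **not** emulate: correlated batch effects across
proteins, intensity-dependent (MA-shaped) ratio compression, isotope
impurity, shared-peptide ambiguity between protein groups, and any
relationship between a protein's true localization and its import index
beyond the planted effects. Passing recovery tests therefore demonstrate
that the ranking and calibration machinery behaves correctly under the
stated statistical model — not that the method's error rates on real
mass-spectrometry data match the simulated ones.

### Named scenarios used in tests and the acceptance script

- **Null**: δ ≡ 0. Reported labels are then uniformly placed in the
  ranking, and the 15%-cutoff Fisher p-value should be non-significant in
  ≥ 90% of seeded runs (it is a valid, discrete—hence super-uniform—test).
- **Perfect separation**: δ = 5, noise sd 0.1, dropout 0. Missingness is
  switched off because this scenario isolates the ranking's ability to
  separate; with dropout on, a planted cargo absent from two runs can never
  be called and recall measures the missingness model instead.
- **Default-parameter recovery**: the 3rd-Z-4% call should be more precise
  and less sensitive than the 2nd-Z-15% call.

Simulations in the test suite and acceptance script run at 300–1500
proteins and 1–12 receptors — large enough for stable order statistics and
enrichment behavior while keeping the whole suite fast; these sizes are the
package's own choice of test scale, and all statistical expectations above
hold at them with margin.

## Known limitations

- Accession identity is the table's string key; isoforms and protein groups
  are not collapsed or resolved.
- The reported-cargo rate is a lower bound on precision under either
  negative definition; no attempt is made to estimate the true cargo
  fraction among unreported proteins.
- Percentile calls carry no per-protein significance; the published
  analysis is rank-based, and so is this implementation.
- Newick export encodes topology and merge heights; no bootstrap or other
  support values are computed.
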