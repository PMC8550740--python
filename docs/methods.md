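# Methods

This note records the models, conventions and design choices behind each
stage, the parameters that matter, and what the synthetic benchmarks do and
do not demonstrate about real survey data.

## Coordinates, formats, genetic codes

All sequence positions are 0-based with half-open windows. FASTA is written
wrapped at 70 columns and read with any wrapping. Genetic codes are the NCBI
tables taken from biopython: table 5 (invertebrate mitochondrial; TGA=Trp,
AGA/AGG=Ser, ATA=Met, stops {TAA, TAG}) is the default for all mtCO1 work,
table 1 is available for comparison. A codon containing any non-ACGT symbol
translates to 'X' and never to a stop: a Sanger ambiguity code must not be
able to push a genuine barcode into the premature-stop filter. This
conservative convention is a repository decision — ambiguity handling before
translation is not standardized in the field.

## Reference panel and the barcode window

A panel is built from ≥ 2 species-labelled, gap-free reference sequences
(in practice mitogenome-derived, hence trusted). The 651-nt barcode window
(217 codons) is fixed on a designated anchor reference and located on every
other reference by global pairwise alignment; references that cannot supply
a gap-free window at ≥ 90% coverage are rejected and reported rather than
silently dropped. The window length of 651 nt is the standard 3′ *mtCO1*
barcode for *Bemisia*; typical PCR amplicons (~864 bp) carry flanks that are
trimmed away.

"Highly conserved regions" are operationalized as amino-acid columns at
which *all* panel peptides agree (the invariance mask). This is the
strictest testable reading; a majority-based mask would be laxer and is not
offered. Consequence: the conserved-site screen can only be as informative
as the panel is deep — a 2-entry panel marks ~all columns invariant and the
screen approaches a simple identity check, while a diverse panel relaxes
exactly the columns that genuinely vary.

## Alignment

Queries are aligned to their nearest reference — nearest by shared 8-mer
count, ties to the lexicographically smallest reference id — with a global
pairwise aligner configured match +1, mismatch −1, gap open −5, gap extend
−1 and free end gaps (biopython's PairwiseAligner; the first reported
alignment is taken, which is deterministic). The stiff gap penalties
reflect the biology: at the ~90%+ identity of conspecific barcodes a true
alignment has no indels at all, so any internal gap the aligner is forced
to open is evidence of a frameshifted pseudogene, not of alignment
ambiguity. Indel calls are window-scoped: gaps strictly inside the barcode
window fail the sequence, flanking (primer-region) gaps are ignored because
flanks are trimmed before translation and cannot affect downstream results.

## QC cascade and its guarantees

Order of verdicts per query: `fail_length` (shorter than 400 nt, or window
identity < 70% = unalignable, or incomplete window coverage) →
`fail_indel` (any internal in-window gap) → `fail_premature_stop` (any stop
among the 217 codons) → `fail_conserved_violation` (non-X mismatch to the
panel consensus at an invariant column) → `pass` with the trimmed 651-nt
barcode and its 217-aa translation attached. Exactly one verdict per
sequence; batch summaries always sum to the input count; the cascade is
deterministic. By construction every planted in-window indel or in-frame
stop is caught (the filters test precisely those properties), and every
unmutated panel member passes against its own panel (its peptide *is* a row
of the profile the mask was derived from). Chimeras are not screened beyond
these filters; a recombination scan is out of scope.

## Distances

p-distance, percent identity (100·(1−p)) and the Tajima–Nei distance all
use pairwise deletion: a site is excluded for a pair only if that pair has
a gap or ambiguity there. Pairwise (not listwise) deletion maximizes usable
sites for Sanger data and matches the common default in barcoding practice.
Tajima–Nei estimates base frequencies q and mismatch-type frequencies x
from the pooled pair, per the original 1984 formulation:

    h = Σ_{i<j} x²ᵢⱼ / (2 qᵢ qⱼ)
    b = ½ (1 − Σᵢ qᵢ² + p²/h)
    d = −b ln(1 − p/b)

Saturation (p ≥ b) raises an explicit error carrying p and b rather than
clamping to infinity, so pathological pairs surface to the caller. Two
independent anchors pin the implementation: on pairs with uniform pooled
composition and all six mismatch types equally frequent, b = 3/4 exactly
and d equals the Jukes–Cantor closed form to machine precision; and d ≥ p
for every valid pair, with equality at p = 0.

The species threshold (next section) is applied on p-distance — the
convention in *mtCO1* barcoding, where the published 4% figure refers to
raw nucleotide divergence — while divergence tables are emitted in all
three metrics so either convention can be audited. Divergence tables that
conflate "percent identity" with a model-corrected distance are ambiguous;
this package never converts one into the other.

## Species assignment and novel-species delimitation

A query is called as the species of its nearest reference iff its minimum
p-distance is strictly below the threshold (default 0.04); at or above the
threshold it is novel (the ≥ rule — a query at exactly 4% is novel, checked
at the exact boundary of ⌈0.04·651⌉ = 27 mismatches). Nearest-reference
ties break lexicographically and are always flagged in diagnostics.

Novel queries are grouped among themselves by single linkage at the same
threshold: two novels belong to one putative species iff a chain of
pairwise distances < 4% connects them. Single linkage is the
least-commitment choice consistent with the threshold rule itself. Group
labels are canonical — groups are ordered by their smallest member id — so
shuffling the input changes no label. Naming continues the numbering
already present in the panel: a group whose nearest reference sits inside
the *B. tabaci* complex (SSA, Africa-Middle East-Asia Minor, or New World
high-level genetic groups) becomes the next SSA number; a group nearest the
Uganda clade becomes the next B. Uganda number. Clade membership is proxied
by the nearest reference's HLGG label; no tree is inferred (Bayesian
phylogenetics is out of scope).

Subgroup calls (SSA1's SG1/SG2/SG3, which differ by only ~1–1.5%) are
nearest-subgroup-reference assignments with the margin to the runner-up
reported, because at sub-percent separations the margin — not just the
winner — is what a careful reader needs.

## Host-association analyses

The host × species matrix counts every assigned fly by the host plant of
its collection record; hosts whose flies all failed QC remain as explicit
zero rows. Composition percentages sum to 100 exactly before rounding.
The minimum-support filter keeps cells with ≥ 3 flies (configurable) and
drops hosts with no surviving cell: a single fly on a plant can be chance,
three is the conventional floor for claiming an association. The
mixed-sample estimator counts, among samples with ≥ 2 assigned flies, those
whose flies span more than one species; subgroups within a species do not
count as a mixture.

## Clustering, k selection, AU support

Host-range profiles are clustered with Euclidean distance and average
linkage by default (correlation distance is offered but raises on constant
profiles). Neither choice is canonical in the literature; both are
configurable and recorded in the run manifest.

The number of clusters is the majority vote of five validity indices —
Calinski–Harabasz, silhouette, Dunn, Davies–Bouldin, C-index — evaluated on
cuts of the same dendrogram over k ∈ {2, …, 10}. The five cover the
variance-ratio, cohesion and separation families; an index that cannot
score any k abstains, and vote ties resolve to the smallest k with a flag.

Cluster credibility uses the multiscale bootstrap. For scales
r ∈ {0.5, 0.6, …, 1.4} the observations (the opposite axis of the matrix)
are resampled with replacement to size round(r·n), the items are
reclustered B times per scale, and each original node's recovery frequency
BP_r (exact leaf-set identity) is fitted by weighted least squares with the
signed-distance/curvature model

    Φ⁻¹(1 − BP_r) = v/σ + c·σ,   σ = √(1/r)

(weights from the binomial variance of BP via the delta method; BP ∈ {0,1}
clamped to 1/(2B) and 1−1/(2B)). The approximately unbiased support is
AU = 1 − Φ(v − c), and BP is reported at r = 1 where Φ⁻¹(1−BP) = v + c.
The sign convention is pinned by two algebraic anchors, both in the test
suite: BP_r ≡ 0.5 forces v = c = 0 and AU = 0.5, and BP generated exactly
from the model is recovered to numerical precision. Degenerate nodes are
special-cased: a node recovered in every replicate at every scale carries
no information about v − c and is reported AU = 1; a node never recovered
is AU = 0 with a flag. With a single scale the model cannot be fitted and
only BP is available (documented degradation). AU > 0.83 marks a node
strongly supported.

One caution, measured on planted-block benchmarks: AU behaves like a
p-value, so among the many *noise* nodes of a dendrogram some will exceed
any fixed cutoff by chance — within-block pair nodes exceeded 0.83 in
roughly half the cases while planted blocks held AU ≈ 1.00 and arbitrary
merges of well-separated blocks held AU ≈ 0.5–0.7. Strong support for a
node is evidence; absence of strong support for its neighbours is not a
guarantee.

## Synthetic data: what it emulates, what it does not

The generator reproduces the survey's design conditions: 651-nt barcodes
descended from a shipped synthetic seed ORF; species separated by ~8%
pairwise (each species receives half the target divergence in substitutions
at mutually disjoint sites, so all pairwise distances land within 1% of
target — placing the full target per species would double pairwise
distances, so the pairwise post-condition takes precedence); within-species
variation ≤ 1% and synonymous-only, so clean queries can never trip the
stop or conserved-site screens; NUMTs with planted in-window 1–2-nt indels
or TAA/TAG stop codons; three flies per sample with a 40% mixture
probability enforced exactly per sample; and specialist-vs-polyphagous
host-preference profiles (default: 80% of a species' probability on its
preferred host). Everything derives from one seeded generator;
identical configs give byte-identical outputs.

Not modelled: transition/transversion bias and codon-position rate
heterogeneity (real conspecific variation is not synonymous-only),
sequencing error and ambiguity codes in queries, chimeric PCR products,
length polymorphism, uneven species abundance, and geographic structure.
Passing the synthetic benchmarks therefore demonstrates the *logic* of the
filters and estimators — 100% detection of planted defect classes, exact
threshold dichotomy, parameter recovery under the design conditions — not
robustness to every artefact of field data. Problem sizes in the bundled
benchmarks (500-sequence QC batches, 300 queries for assignment, 16×12
matrices with B = 1000 bootstrap replicates, 300-sample surveys) were
chosen to exercise every code path at desk scale.

## Numerical and degenerate-input conventions

Distances with no comparable sites raise rather than return NaN. All-zero
count matrices refuse composition; degenerate (all-profiles-identical)
matrices refuse k selection; correlation distance refuses constant rows,
naming them. Dendrogram export is Newick with branch lengths equal to
merge-height differences. The assignment threshold must lie in (0, 0.5).
Seeds derived from a user seed stay below 2³¹.
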