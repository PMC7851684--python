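# Methods

## The problem

PCR-based detection of accessory genes — here motivated by multidrug
resistance efflux pumps (MDREPs), which move on mobile genetic elements
and diverge quickly — needs primer panels that stay "universal" across a
community of genomes without producing false positives from off-target
binding. `crossprime` implements the two design strategies for such
panels, the conservation statistic that chooses between them, and a
genome-wide in-silico audit of any panel against explicit binding rules.

## Conservation scoring

Given a family multiple-sequence alignment (MSA), each sequence is scored

    percent identity = matches × 100 / alignment length (including gaps)

and families are summarized as mean ± SD (sample SD, ddof=1). "Matches"
for more than two sequences is not uniquely defined; the package defaults
to **match-to-column-majority** (gaps never win a majority; ties break
alphabetically A<C<G<T), with `pairwise_mean` as an alternative mode.
The consensus reading is consistent with the short-fragment skew this
denominator is designed to expose: a 200-nt fragment inside a ~4000-column
family alignment can score at most ~5% regardless of how well its
residues match, flagging fragmentary annotations.

Because the denominator includes gap columns, appending k all-gap columns
multiplies every score by L/(L+k); this is asserted as a property test.

**Routing rule:** families scoring ≥ 75% use the consensus approach (A),
below 75% the per-gene approach (B). The boundary value 75.0 routes to A
(a documented tie decision; the published guidance is stated as an open
interval on both sides).

## Primer design

Shared constraints (defaults, all configurable through
`DesignConstraints`): primer length 18–23 nt; product size 180–240 bp
(qPCR-friendly); GC target 50% as a soft penalty with a hard 80% cap;
pair ΔTm ≤ 5 °C, enforced strictly — infeasibility is reported with the
most frequently violated constraint rather than silently relaxed.

**Approach A** ranks gap-free alignment windows by the degeneracy of
their minimal covering IUPAC consensus and selects the forward/reverse
window pair minimizing total degeneracy (forward × reverse), requiring
the per-row *ungapped* product size to be in range for **every** row.
Ties break by Tm-midpoint closeness between the two primers, then
leftmost forward window, then leftmost reverse window, then shorter
windows. The informal design goal — minimize the number of mismatches
against the family — is formalized as minimizing the expansion count,
the quantity that actually drives off-target load. Windows overlapping any gap-containing column
are excluded in all rows (the permissive reading — gap-free in *most*
rows — is not implemented). ΔTm for degenerate primers compares
midpoints of the min–max Tm ranges.

**Approach B** designs one non-degenerate pair per gene with product
size exactly S, searching S exhaustively over 180–240 (61 values — no
heuristic needed). S is chosen to maximize the number of designable
genes; ties break by smaller total |GC−50| penalty, then smaller total
pair ΔTm ("Tm spread" read as the panel sum of per-pair deltas), then
smaller S. Within a gene, the minimal-penalty pair is chosen
lexicographically by (GC penalty, ΔTm, forward start, forward length,
reverse length) — the per-gene tie order is this package's choice, and
it makes both design operations pure functions: reruns are bit-identical.
Genes with no feasible pair at the chosen S are listed, not dropped.

Reverse primers are always stored 5′→3′ on the antisense strand;
product size counts both primers inclusively (forward 5′ to reverse 5′).

## Thermodynamics

Concrete-sequence Tm uses the unified SantaLucia nearest-neighbor
ΔH/ΔS parameters with initiation terms (via Biopython's
`MeltingTemp.Tm_NN`), the SantaLucia-1998 entropic salt correction, and
defaults of **50 mM monovalent salt** and **250 nM primer** (primer in
excess; no Mg²⁺/dNTP correction). The platform that produced the
published panel does not document its settings; these defaults reproduce
all 69 non-degenerate published panel Tm values within ±2.5 °C (mean
offset +1.8 °C) and were frozen before the acceptance tests were run.
All four parameters are configurable (`ThermoParams`). Degenerate
primers report Tm and GC as min–max ranges over their expansions (the
panel's convention), never averages; range endpoints are exhaustive over
expansions, capped at 4096 by default. GC rounding is half-up to match
the panel's integer column. Inosine is unsupported.

## Binding-site audit

A site is an **ungapped, full-primer-length** alignment of one concrete
expansion against the template (the binding vocabulary has no
insertions/deletions). All rules must hold:

* matches ≥ 18 (17 in `CONTROL_RULES`, used to validate the short
  control primers), mismatches ≤ 3 — jointly, an 18-mer admits 0
  mismatches, a 20-mer 2, a 21–23-mer 3, and identity is always > 80%;
* no two consecutive mismatches;
* matched 3′ terminal base, and matched 5′ terminal base (the 5′
  exclusion the original workflow applied manually is automated here);
* site temperature within 30–100 °C.

Site temperature is modeled as the expansion's perfect-duplex Tm minus a
flat **5 °C per mismatch** (configurable, 0 disables): the per-site
temperatures printed by the original platform come from an undocumented
formula, so a transparent penalty model is used instead. Degenerate
primers are deduplicated to one report per (position, strand), keeping
the expansion with the most matches (ties: lexicographically smallest).
Template N never matches any primer base. Internally all coordinates are
0-based half-open; report output is 1-based inclusive.

Amplicons are predicted from convergent opposite-strand site pairs with
the plus-strand site upstream; product size spans the two 5′ ends
inclusively and is capped at 5 kb by default. Same-strand pairs — e.g.
two downstream primers bound at the identical location — never amplify.
Hits are classified into the reporting bins used throughout: identity
{100%}, [90.0, 99.9%], [80.0, 89.9%] (on identity rounded to 0.1) and
5 °C temperature bins from ≤49.9 to ≥70.0. Sites are annotated to the
feature containing their midpoint, else "noncoding region"; the various
"unknown function" product labels are collapsed to one "hypothetical
protein" category.

## Synthetic data

`crossprime.synth` fabricates everything the tests need: gene families
(one ancestor, each copy mutated i.i.d. per site at rate *d*,
substitutions only, uniform over the three alternatives), random
backgrounds at a chosen GC, and planted binding sites. Under this model
the expected pairwise identity is closed-form,
E[id] = 1 − 2d(1−d) − d²·(2/3), verified by Monte Carlo. Defaults state
the emulated world: 6 community members, 1.5-kb genes, divergence 0.2
(~65% pairwise identity, within the observed efflux-family range),
50-kb backgrounds at 50% GC — backgrounds are desk-scaled stand-ins for
megabase genomes, chosen so the full suite runs in seconds on one CPU.

Planted compliant sites carry scattered internal non-adjacent mismatches
and are scanner-recoverable by construction; decoys violate exactly one
named rule (adjacent mismatches, 3′ mismatch, 5′ mismatch, or one
mismatch over budget) and must never be reported at their coordinates.
The substitution-only model means planted identities are exact
arithmetic — what a green test establishes is rule fidelity and
coordinate bookkeeping, **not** robustness to indels, rearrangements, or
real annotation noise, which this generator does not emulate. All
randomness flows from explicit seeds; community fixtures regenerate
bit-identically from their manifest.

## External alignment

MAFFT is invoked, never reimplemented, with the stated default
conditions (`--retree 2 --maxiterate 0 --op 1.53 --ep 0.0`); a missing
executable raises a capability error instead of falling back silently.
All scoring tests use precomputed or constructed alignments, so the
suite does not depend on aligner version behavior.

## Known limitations

* The printed Tm range of the degenerate control-panel upstream primer
  (51.1–66.0 °C) is **not** reproducible as a min/max over its 512 IUPAC
  expansions: under the same defaults that reproduce every concrete
  panel Tm, the exhaustive maximum is ~70.8 °C. The printed range was
  evidently computed over the member sequences rather than all
  expansions. The corresponding acceptance test asserts the stated
  tolerance faithfully and is expected to fail; the qacA1/3 degenerate
  range (58.3–61.8 °C) does verify endpoint-wise.
* One published GC cell (P. putida norM downstream: printed 60, actual
  55 from its own sequence) is internally inconsistent; the ±1-point
  agreement criterion is asserted over the panel at the ≥90% level.
* Hit counts for degenerate primers depend on whether expansions are
  counted separately; this package reports one site per (position,
  strand). Published hit-count tables are therefore qualitative, not
  exact, reproduction surfaces.
* No secondary-structure, hairpin, primer-dimer, or extension-efficiency
  modeling; no Mg²⁺/dNTP Tm corrections by default; no PCR kinetics.
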