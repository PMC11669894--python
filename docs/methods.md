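# Methods

This note documents the models, numerical choices and limitations behind
`kellvar`. It describes what the code computes and why; every number quoted
here is produced by the test suite or by `scripts/acceptance.py`, not
asserted from memory.

## Variant catalog

A variant is identified by its substitution key `(position, wt, var)` in
1-based protein coordinates of the 732-residue Kell sequence (UniProt
P23276). ISBT allele names are attributes, not identities: one substitution
can define several alleles (Pro560Ala appears under both a KEL*01 and a
KEL*02 null allele) and one allele can carry two substitutions in cis (the
two-variant null and mod alleles, and the two-residue KEL:35 antigen).
Labels (NullV, ModV, AgWT, AgV, MinusAllele, CtrlV) are merged across the
three source tables, so a substitution like Leu329Pro is simultaneously a
mod-expression variant, an antigenic wild-type position and a minus allele.

Counting conventions, chosen to match how the published totals are tallied:

* *Distinct substitutions* deduplicate on the substitution key (101 across
  all tables; 18 null, 24 mod, 32 antigen-table, 31 control).
* *Single-exchange-causal* flags substitutions attributable to that exchange
  alone: rows flagged as acting only in combination with the common
  Thr193Met or Arg281Trp backgrounds, and members of two-in-cis alleles,
  are excluded. A variant is causal if at least one of its alleles
  attributes the phenotype to it alone (14 null, 17 mod).
* *Antigen counts* are antigen-level: the AgWT and AgV totals (22 and 14)
  count distinct KEL antigen names, so the two-residue KEL:35 counts once
  and the weak KEL:1 variant counts as an antigenic variant. The arginine
  count (11) is position-level: distinct AgWT positions whose wild type is
  arginine.
* Controls require a recorded European minor allele frequency at or above
  3.0×10⁻⁵ — frequent enough that antigenicity would have surfaced
  clinically. Variants without a frequency are never promoted to controls;
  `apply_maf_filter` reports them separately, and a generic row without any
  class label becomes `Uncharacterized` rather than silently dropping out.

## Solvent accessibility and burial

Accessible surface area uses the rolling-probe sphere-point construction:
each heavy atom's probe-expanded sphere (van der Waals radius + 1.4 Å) is
covered with a golden-spiral lattice of 960 quasi-uniform points, and the
accessible fraction is the share of points not inside any neighbouring
expanded sphere. Neighbour lookup uses a k-d tree; hydrogens are ignored
and hetero atoms (e.g. the active-site zinc) are excluded from occlusion by
default, toggleable. Residue ASA is the sum of its atoms' areas.

Accuracy at the default quadrature: a lone sphere reproduces the closed
form 4π(r+p)² to ~10⁻⁶ relative error, and on random 20-atom clusters the
total area agrees with an independently coded Monte Carlo surface
integration at 10× point density to well under 2% (the acceptance script
reports the realized error, typically ≈0.3%).

RSA divides residue ASA by a residue-specific theoretical maximum
(Gly-X-Gly extended-tripeptide reference values, Tien et al. 2013), clamped
at 1.0. Burial classes partition [0, 1] half-open: buried [0, 0.05),
half-buried [0.05, 0.25), exposed [0.25, 1]; each boundary belongs to the
upper class. RSA values published for specific Kell positions depend
strongly on the structural model and on the (unknown) normalization of the
external service that produced them — e.g. one antigenic position differs
by a factor of four between the two published models — so matching those
specific values is a documentation-level comparison, not a test.

Topological domains (cytoplasmic 1–47, transmembrane helix 48–67,
extracellular 68–732) are assigned from configured intervals. The
membrane-proximal/membrane-distal subdomain boundaries are model-derived
and not published as intervals; the default config ships them empty, and
every rule that references them degrades to "unknown" rather than guessing.
Membrane proximity, when a membrane plane is supplied (point + normal), is
a signed distance along the normal below a 15 Å threshold.

## Conformational epitope clustering

Antigenic sites are clustered by single-linkage connected components of the
Cα distance graph at a 12 Å cutoff — chosen so that the two helices known
to carry co-localizing antigens on the published model (sites 248/249/253/260
with the 379–392 helix) join one cluster, and configurable. Components are
reported with their sequence segments (maximal consecutive runs), spatial
diameter, and buried members (RSA < 0.05) flagged as indirect contributors:
a buried substitution can still shape a surface epitope through local
conformational change. Sites without coordinates are listed as
unclusterable rather than silently dropped. Increasing the cutoff can only
merge clusters, never split them (regression-tested against a brute-force
pairwise-threshold oracle).

## Conservation

Ortholog conservation of a reference position is the percentage of
ortholog rows (the human reference row is excluded from the denominator;
39 in the published 40-sequence alignment) carrying the identical residue
in the aligned column; gaps count as mismatches, and no similarity classes
are applied — the published scores are plain percent identity.
Structural conservation is the number (0–3) of homolog structures (ECE-1,
NEP, Zmp1) whose spatially corresponding residue, taken from user-supplied
correspondence maps, is identical. Computing the structural alignments
themselves is out of scope; the maps are inputs. A position absent from a
map contributes zero for that map, while supplying no maps at all leaves
structural conservation unknown — the distinction matters for the rule
engine's tri-state logic.

The guideline's "sequentially conserved" condition defaults to ≥90%
ortholog identity. The threshold is deliberately configurable: the source
analysis never quantifies "conserved", and 90% sits between the
near-perfect conservation of expression-critical positions and the broad
spread of control positions.

## Substitution property scores

Each AAIndex-style scale is Z-standardized over its 20 standard amino acid
values (mean and σ over exactly those 20 numbers — the formula's x̄ and σ
are otherwise underdetermined), and a substitution scores

    ΔZ = (v_var − x̄)/σ − (v_wt − x̄)/σ = (v_var − v_wt)/σ.

The shipped hydrophobicity scale (PRAM900101) is a transfer free energy in
kJ/mol where lower values mean stronger hydrophobicity; it is marked
inverted, so its ΔZ is sign-flipped and positive ΔZ consistently reads
"more hydrophobic". Identity substitutions score 0 and ΔZ(a→b) = −ΔZ(b→a)
exactly (verified over all 380 ordered pairs per scale).

Flags feeding the guideline's property-change condition:

* proline involvement — proline on either side of the exchange;
* volume change — |ΔZ| on the side-chain volume scale (GRAR740103) at or
  above 0.5, an unquantified notion in the source; 0.5σ ≈ 21 Å³ separates
  conservative exchanges (Leu↔Ile, Ala↔Ser) from the smallest changes the
  analysis treats as meaningful;
* surface charge change — any charge-category transition (Arg/Lys/His
  positive, Asp/Glu negative; histidine counted positive as the simplest
  consistent table, configurable) at a half-buried or exposed position;
* buried hydrophobic→hydrophilic and exposed hydrophilic→hydrophobic —
  the dichotomy is the sign of the inversion-corrected hydrophobicity
  Z-score, since no residue list is published.

The polarity scale (GRAR740102) is computed and reported but feeds no
default rule condition; it is retained for the group-comparison outputs.

## Group statistics

Two-sample comparisons use the Wilcoxon–Mann–Whitney test in its normal
approximation: U from midranks, tie-corrected variance
n_a·n_b/12·[(n+1) − Σ(t³−t)/(n(n−1))], two-sided p from the standard
normal. Continuity correction is off by default (the source does not state
whether it was applied) and toggleable. Two-sided tests, no
multiple-testing correction — significance bands (*, **, ***) annotate raw
p-values at 0.05/0.01/0.001. When every pooled value is tied the statistic
is degenerate and p = 1 is returned with a warning. IQR summaries use
linear-interpolation ("type 7") quantiles, fixed for reproducibility.

Small-sample accuracy, measured exhaustively against full permutation
enumeration on tie-free configurations: without continuity correction the
worst |p_asym − p_exact| is 0.19 for groups of ≥3 (and much worse below);
with continuity correction it falls to ≤0.02 once both groups have ≥5
values. The asymptotic form is therefore trustworthy at the class sizes
the catalog actually produces (14–32 per class) but should not be read as
exact below ~5 per group; the enumeration oracle is exported for such
cases.

## Annotation rule engine

The seven guideline conditions are evaluated tri-state: true, false, or
unknown when an input is missing (no conservation profile, no MPC score,
no membrane plane, no epitope model...). Unknown never counts as satisfied
and never counts against a variant — partial annotation must not bias
toward "neutral".

The published guideline lists conditions but not their boolean
combination. The default strategy encodes the narrative the analysis
itself draws:

* **destabilizing** — burial ∈ {buried, half-buried} AND (sequence- OR
  structure-conserved) AND a property-change flag;
* **antigenic** — burial ∈ {half-buried, exposed} AND location not
  affirmatively excluded (inside the tolerant central cavity or
  membrane-proximal) AND (hotspot residue OR surface charge change OR
  inside a predicted epitope segment);
* **neutral** — neither rule fires and the property-change and hotspot
  conditions are affirmatively false;
* **indeterminate** — anything else (in particular, a variant with all
  conditions unknown).

This combination is the module's central interpretive decision and is fully
configurable. Conditions 1 (known Kell position) and 7 (MPC > 0.4) add to
the evidence score — the count of affirmatively satisfied conditions, used
to rank screening output — but never decide a verdict alone. The default
epitope segments are the nine sequence intervals of the predicted
conformational epitopes (139–147, 244–260, 287–299, 300–310, 322–333,
379–392, 399–407, 483–496, 589–601); the cavity position list defaults to
empty because the tolerant central cavity was identified visually, not as
a printed residue list. Cohort screening routes substitutions already in
the catalog to a known-allele report and ranks the rest by evidence score
(descending, ties by position); reports are byte-deterministic for
identical inputs.

## Synthetic data

The generators exist to give every pipeline stage a controlled ground
truth. Structures are toy models: a dense pseudo-globular core of
five-atom residues (Cα plus four tetrahedral stubs) on a jittered cubic
lattice buries its innermost residues; exposed residues sit on isolated
surface stalks; half-buried residues are placed by per-residue bisection
of their radial offset until the package's own scorer puts them in
[0.05, 0.25). This packing was chosen over idealized helix bundles because
it controls per-residue burial class far more tightly, and only the RSA
contrast — not backbone realism — carries information here. Realized
classes are verified internally with the same ASA engine the pipeline
uses, with bounded retries at tighter packing before an error.

MSAs set each planned column to round(target% × n_orthologs) matching rows
(within 1/n per construction; n = 39 by default, matching the ortholog
panel); mismatching rows draw a random different residue. Variant sets
draw from three archetypes mirroring the observed class signatures:
destabilizers (buried wild types, 92–100% conservation, proline or large
volume changes), antigens (exposed wild types, 40–80% conservation, charge
changes or hotspot residues), and neutral controls (exposed, conservative
exchanges with no flags). One integer seed drives everything;
identical seeds give identical bytes.

What the synthetic benchmark does and does not show: the default cohort
(seed 1, 10 variants per class) is recovered at 100%/100% with 0% false
non-neutral calls, which validates the plumbing — context computation,
conservation scoring, flag logic and rule combination fire as designed on
inputs that match the archetypes. It does not measure performance on real
variants, whose burial, conservation and property signals are correlated,
noisy and model-dependent; the published evidence for the rules is the
class-level contrast analysis, not this benchmark.

## Known limitations

* RSA values for specific Kell residues are reproducible only approximately
  and model-dependently; the package treats published per-residue values as
  context, not test oracles.
* The rule combination is an interpretation; the source lists conditions
  and a selection outcome but no boolean formula, and its final
  expert-curated screening list is in supplementary material not consumed
  here.
* The asymptotic rank test is a poor approximation below ~5 values per
  group (see above); use the enumeration oracle there.
* Correspondence maps, membrane planes, cavity lists and MPC scores are
  inputs; the package computes none of them.
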