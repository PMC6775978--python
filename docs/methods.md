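# Methods

## Catabolic energetics

### Model

A reaction is a signed stoichiometry over named aqueous species plus the
number of electrons transferred per formula unit as written. Validation
enforces element balance, charge balance, and that the declared electron
donor and acceptor appear as reactants. The in situ Gibbs energy is

    ΔG_r(T) = ΔG°_r(T) + RT ln Q

with R = 8.314462618×10⁻³ kJ·mol⁻¹·K⁻¹. ln Q sums ν_i·ln a_i over
participants: solute activity is γ·m (molality), the solvent activity is
fixed at 1, and H⁺ activity is 10^(−pH). Per-electron yields divide ΔG_r
by the electrons transferred, which makes reactions of different
stoichiometry comparable and leaves the value invariant under rescaling
the written reaction.

### Temperature correction

Standard reaction energies at temperature come from 298.15 K formation
properties by the Gibbs–Helmholtz relation assuming constant reaction
enthalpy (the van 't Hoff approximation):

    ΔG°_r(T) = (T/T_ref)·ΔG°_r + (1 − T/T_ref)·ΔH°_r

This is standard practice below ~70 °C, where the neglect of ΔCp is a
small correction relative to the concentration terms, and it is fully
reproducible from tabulated ΔG°f/ΔH°f alone. Full revised-HKF /
SUPCRT-style property calculation and pressure corrections are out of
scope; pressure is treated as metadata only.

### Species table and reactions

The shipped table (`crustbio/data/species.tsv`) carries ΔG°f and ΔH°f at
298.15 K for CO(aq), H₂(aq), CH₄(aq), acetate⁻, HCO₃⁻, SO₄²⁻, HS⁻,
H₂O(l) and H⁺, transcribed from the Amend & Shock (2001) / Shock &
Helgeson aqueous-organism compilations (1 molal standard state for
solutes; H⁺ by convention zero). It is data, not code: any TSV with the
same columns can replace it.

The four shipped reactions couple sulfate reduction to CO, H₂, CH₄ and
acetate oxidation, each written per mole of SO₄²⁻ (8 electrons), with
bicarbonate as the carbon product and water as unit-activity solvent —
the aqueous, circum-neutral convention. E.g.

    4 CO + SO₄²⁻ + 4 H₂O → 4 HCO₃⁻ + HS⁻ + 3 H⁺

The three protons released per sulfate are why CO dominates the
per-electron ranking at circum-neutral pH: at pH 7.5 the H⁺ product term
contributes ≈ −48 kJ per mole of H⁺ at 337 K.

### Conditions and defaults

The default profile `jdfr` encodes a warm ridge-flank crustal aquifer:
T = 337.15 K (64 °C) and SO₄²⁻ = 0.018 mol/kg are field-constrained;
pH 7.5, ionic strength 0.7 mol/kg, HS⁻ 10⁻⁵, HCO₃⁻ 2×10⁻³ and all donor
baselines 10⁻⁶ mol/kg are **documented placeholders** — plausible values
for altered seawater in basement, not measurements — and every field is
overridable in the profile file or per call. Donor sweeps default to
10⁻⁸–10⁻⁴ mol/kg, the range of CO/acetate concentrations reported for
comparable marine and fluid-rock environments. Whether a given donor
should use a measured in situ concentration or the sweep is a per-analysis
choice; both are supported by overriding the profile.

The activity model defaults to ideal (γ = 1). The Davies equation,
log₁₀γ = −A·z²·(√I/(1+√I) − 0.3·I), is available with A held at its
298.15 K value of 0.509; over 273–340 K the true variation of A (~6%)
is far below the uncertainty introduced by the placeholder ionic
strength, so a temperature table is not warranted at the ideal-default
setting. Neutral species and I = 0 give γ = 1 exactly.

### Numerical behavior

All energies are closed-form linear algebra on small dictionaries; the
only tolerances in play are float round-off (tests assert 10⁻⁹ kJ on
identities such as equilibrium ΔG = 0, scale invariance and sub-reaction
additivity). Donor ranking sorts by per-electron yield ascending with
lexicographic tie-breaks on reaction id, making the order fully
deterministic.

## Marker profiling

A marker set is a named list of gene symbols and/or KO identifiers with a
rule (`any`, `all`, `fraction≥θ`) and an expectation (`present`, or
`absent` for negative assertions such as the mcr set, whose absence is
evidence against methanogenesis). Grouped subunit strings (`fwdABCDEFG`)
expand to per-subunit members at load time so completeness fractions have
per-subunit resolution. Matching is symbol-first (case-insensitive), then
exact KO. Completeness is (#members present)/(#members); for
absence-expectation sets the report shows NaN completeness because
absence is an assertion, not a pathway fraction. The lineage summary is
the union of presence over genomes — the appropriate collective view when
every individual genome is incomplete. The shipped set file transcribes
the Hydrothermarchaeota pathway inventory (Wood–Ljungdahl, sulfate and
nitrate reduction, CO oxidation, CODH/ACS, Ni-Fe hydrogenase maturation,
glycolysis/gluconeogenesis, RuBisCO, and the mcr negative set) and is
editable data. One disambiguation: the glycolysis list distinguishes
`pmm` (phosphomannomutase/phosphoglucomutase) from `pgm` (phosphoglycerate
mutase) so the nine members are distinct and a genome missing only
pyruvate kinase scores 8/9.

## Motility comparison

The statistic is the fraction of COG-annotated genes assigned to category
N (cell motility). Design choices, fixed for determinism and documented
because the convention is not standardized:

- Denominator = genes with ≥1 COG category letter, not all predicted
  genes. Configurable in the sense that the caller controls which
  annotations reach the tally.
- Multi-letter category strings increment each category once and the
  denominator once, avoiding silent undercounting.
- Completeness filter is inclusive (≥ threshold, default 10%);
  metagenomes carry no completeness and always pass.
- Quartiles use the inclusive-median (Tukey hinge) method: with the data
  sorted, each half includes the middle observation when n is odd.

An experimental `motility_ra_per_completeness` column (raw fraction
divided by completeness/100) is emitted alongside the raw fraction for
users who want to correct partial genomes toward a common footing; it is
flagged experimental because the correction assumes motility genes are
uniformly distributed over the genome.

## Assembly statistics

- Contig filter: strict `>` cutoff by default (matching the ">2 kbp"
  submission convention), inclusive variant available.
- N50: smallest length L such that contigs ≥ L sum to at least half the
  total (descending-cumulative convention), property-tested against a
  brute-force oracle.
- GC: 100·(G+C)/(A+C+G+T), N excluded from the denominator; any base
  outside A/C/G/T/N is an error rather than silently dropped.
- Complete-genome size: assembly_size/(completeness/100); reported
  extrapolations round to two significant figures. Per-genome values plus
  mean and median are reported because which aggregation a study intends
  is often unstated; here the mean over the five single-cell genomes is
  the headline 1.8 Mbp figure.
- Proportions round half away from zero on report (42% from 28/66, 24%
  from 23/94).

## Synthetic data

The generator emulates IMG-style per-genome annotation exports and
assembly FASTA, with machine-readable truth emitted alongside so recovery
tests never re-derive truth from the data:

- Each genome gets a configurable number of COG-annotated genes
  (default 1000, within the range of real partial archaeal genomes);
  category N is assigned to a Binomial(n, p_env) subset and background
  genes draw uniformly from 16 non-motility categories.
- Default cohort: 30 genomes per environment with p = 0.03 (crustal
  aquifer) vs 0.005 (sediment) — the contrast the comparison is designed
  to resolve; at n = 1000 the per-genome binomial spread (σ ≈ 0.005)
  leaves the two interquartile ranges well separated.
- Planted marker genes are appended exactly once per member symbol and
  carry no COG category, so planting an inventory does not perturb the
  COG-annotated denominator or the motility fraction.
- Contigs draw log-normal lengths (default μ = 9, σ = 1 on the natural
  log scale, median ≈ 8 kb) and i.i.d. bases with P(G or C) = target, so
  a ≥100 kb batch concentrates within 1% of the target GC.
- Determinism: one root seed; per-genome streams come from
  `SeedSequence(seed, spawn_key=(index,))`, so adding a genome to a spec
  leaves previously generated genomes byte-identical.

What the generator does **not** emulate: real gene-length and COG-category
composition, annotation error, amplification bias, assembly chimerism, or
phylogenetic covariance between genomes. Passing recovery tests therefore
demonstrates that the estimators and scoring are correct computations,
not that annotation pipelines are unbiased on real data.

## Interface conventions

All tabular output is TSV (UTF-8, LF) with floats at 9 significant
digits, which round-trips bit-stably; JSON summaries are key-sorted.
Every CLI run writes a provenance block (tool version, command,
parameters, config hash). Outputs are pure functions of (inputs, seed).

## Known limitations

- The thermodynamic engine ignores pressure and ΔCp; below ~70 °C and at
  seafloor pressures both corrections are small next to the uncertainty
  in the placeholder fluid composition, but results at the default
  profile should be read as scenario calculations, not measurements.
- Speciation is not solved: bicarbonate stands in for total DIC and the
  user is responsible for supplying speciated molalities.
- Marker scoring trusts the input annotations; it performs no homology
  search, and a symbol mismatch between annotation pipelines will read
  as absence.
- The quartile and N50 conventions are fixed choices among several in
  circulation; comparisons against numbers computed under other
  conventions can differ at the margin.
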