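# Methods

## Mass arithmetic

Monosaccharide masses are derived from elemental formulas (Hex C₆H₁₂O₆,
HexNAc C₈H₁₅NO₆, dHex C₆H₁₂O₅, Neu5Ac C₁₁H₁₉NO₉) using CODATA
monoisotopic masses and IUPAC standard atomic weights as shipped with
pyteomics. *Free* masses are the free sugars; *residue* masses subtract
one water (18.0106 Da mono / 18.0153 Da average). Because every
glycosidic bond — including the Asn–GlcNAc attachment — condenses out one
water, an intact glycopeptide mass is exactly peptide mass + Σ residue
masses, and glycan mass arithmetic is strictly additive. The rounded
average free masses are Hex 180, HexNAc 221, Neu5Ac 309; dHex is 164.16,
although it is often lumped with the "~180 Da" hexoses in informal
descriptions — we implement the correct formula mass.

The ¹⁸O glycosite marker is pure elemental bookkeeping on the Asn→Asp
side-chain conversion (−NH₂, +OH): +0.98402 Da monoisotopic with ¹⁶O,
+2.98826 Da with the ¹⁸O label (nominal +1 vs +3 Da). On the average
scale the label oxygen keeps its exact isotope mass — a label is not an
isotope mixture.

Cysteines are treated as carbamidomethylated throughout (the fixed
modification of a standard reductive-alkylation workflow); oxidation and
deamidation are supported as variable modifications. Peptide identity for
shift analysis is the *bare sequence*: these modifications change mass by
far too little to move a peptide across SEC fractions.

## SEC model

Elution volume is linear in log₁₀(mass) — the standard SEC calibration —
with negative slope, anchored so that `mass_high` elutes at the start of
the collection window (10 mL) and `mass_low` at its end (20 mL); 20
fractions of 0.5 mL are binned half-open, with the lower mass anchor
assigned to the last fraction. Masses outside the calibrated range clamp
to the window edges with a logged warning (very large species elute in
the void); average-scale masses feed the model, since hydrodynamic
behaviour tracks total mass. Peak width, tailing, hydrophobicity and
charge are deliberately out of scope: only mass drives the fraction.

**Default calibration: 1500–4000 Da.** The column's nominal separation
span (100–7000 Da, available as `SECCalibration.column_nominal()`) would
give a slope of −5.4 mL/decade, far too shallow for a two-monosaccharide
change to move any glycopeptide two fractions — no deterministic
log-linear model over that span can reproduce the method's observed
resolution. Real glycopeptide SEC runs resolve a much narrower effective
mass range than the nominal span; we therefore anchor the default
calibration at 1500–4000 Da (slope −23.5 mL/decade), chosen jointly with
the simulator's observable mass window (below) so that a ≥ 324 Da glycan
change shifts ≥ 2 fractions everywhere in the window, while a single
hexose (162 Da) does so only below ~1.6 kDa — two monosaccharides always,
one monosaccharide sometimes. All calibration parameters are plain config.

`min_detectable_change` inverts the binned model by bisection on the mass
gain (the binned shift is monotone non-decreasing in the gain), to 1e-6 Da,
returning infinity when the base species already elutes too close to the
void to shift further.

## Classification rule

Differential ⇔ |Δfirst| ≥ 2 or |Δlast| ≥ 2 on integer fraction numbers
(equivalently, "absolute difference larger than 1"; the threshold is the
configurable `min_shift`). Sign convention Δ = control − treated, so
positive = treated eluted earlier = "upgraded". First- and last-elution
statistics are counted independently in the histograms: a peptide may be
upgraded in one and downgraded in the other and contributes to both.
Single-condition peptides are NA everywhere and excluded from in-both,
differential and histogram counts. The localization-probability cut is a
strict `> 0.75`; the drop reason recorded for a filtered row is the first
failing rule in the order reverse, contaminant, localization.

Known-glycosite matching is exact on (leading accession, 1-based
position); an opt-in fallback strips isoform suffixes ("P01234-2" →
"P01234") since catalogues usually list canonical sequences. When a site
row lists several accessions, the leading (razor) accession is used.

## GO branch filtering

Offspring of a root term is the transitive closure of inverted `is_a` and
`part_of` edges, root-inclusive, computed by a memoized iterative
traversal; the DAG is validated acyclic on load and obsolete terms are
excluded. Regulates-type relations are ignored. A peptide with several
gene names gets the terms of the first gene (alphabetical within a
profile) with a non-empty annotation; the membrane flag is true iff any
assigned term lies on the branch. Gene-symbol matching is case-sensitive
and exact.

## Simulator

The simulator generates the *inputs* to the pipeline with known truth,
emulating, per condition: a proteome of unique tryptic peptides (length
7–12, C-terminal K/R, no N-terminal proline), glycosites only on
N-X-(S/T) sequons with X ≠ P (exactly one per glycopeptide; peptide
bodies contain no other Asn so truth is unambiguous), control glycans
drawn from a high-mannose-weighted pool (Man5–Man9 plus a tail of
hybrid/complex forms), lectin capture modelled as Hex count ≥ 3 (the
trimannosyl-core requirement of a mannose-binding lectin), a treatment
effect on 30% of sites drawn from a mass-gain-biased pool of
two-to-three-monosaccharide deltas, deterministic fraction assignment of
the *intact* glycopeptide mass through the SEC model with a one-fraction
elution tail (`elution_spread=1`, so min/max logic is exercised while
truth stays recomputable from composition + calibration alone),
per-(peptide, condition, fraction) Bernoulli dropout (default 10%), a
localization-probability mixture (15% of observations below the 0.75
cut), decoy and contaminant rows at 5% each, occasional duplicate
peptide-ID links (10%) to exercise row explosion, a synthetic
known-glycosite catalogue covering 70% of emitted sites (the typical
fraction of previously catalogued sites in such experiments) plus fake
entries, and a small synthetic GO cellular-component ontology with a
plasma-membrane branch (both `is_a` and `part_of` children) annotated to
42% of genes.

Only glycopeptides whose intact mass falls in the observable window
(1600–3400 Da) in at least one condition are emitted — species outside it
elute outside the collection window or the MS detection range. Together
with the default calibration this window guarantees that every injected
≥ 2-monosaccharide effect is detectable, so noise-free recovery
(sensitivity = specificity = 1) is a meaningful correctness check rather
than a tautology, and single-monosaccharide effects are recovered only
partially (~40–60% at the default conditions).

All randomness flows from one seed through a single NumPy generator;
identical config ⇒ byte-identical fixture. What passing tests on
simulated data do *not* show: robustness to shared peptides, realistic
sequence composition, chromatographic peak shapes, intensity-dependent
detection, or search-engine scoring behaviour — none of which are
modelled.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulator at its default
scale (50 proteins × 8 peptides ≈ 310 emitted glycopeptides, 20
fractions), which exercises every code path in a few seconds. Exhaustive
rule checks cover the full 1..20 min/max fraction grid; property-based
checks (hypothesis, derandomized) cover label-swap symmetry, mass
additivity and offspring-vs-reachability on random 50-node DAGs. Float
comparisons in tests use absolute tolerances well below the quantities'
printed precision; fraction binning guards the floating edge of the last
bin explicitly.

## Known limitations

- The calibration constants of any real column must be measured; the
  defaults encode the resolution behaviour, not a particular instrument.
- Counts that depend on external catalogue/ontology versions (e.g. how
  many differential sites are "known" or plasma-membrane) are
  reproducible in logic but not in value against any published dataset.
- One profile per sequence means a multi-glycosite peptide contributes a
  single differential call carrying all its sites' metadata; site-level
  attribution within such a peptide is not attempted.
- OBO parse errors are reported with the file path but not the offending
  line number (a limitation of the underlying parser).
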