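# Methods

## The problem being modelled

Bottom-up MS analysis of histones derivatizes lysines (propionyl or
d3-acetyl) before trypsin digestion and caps peptide N-termini (phenyl
isocyanate or propionyl), producing an ArgC-like cleavage pattern.  A
search engine's candidate peptides therefore already carry chemistry, and
the delta mass of an open search is the *net* shift between the observed
peptidoform and a derivatized candidate.  Biological acylations and
glycation adducts occupy the lysine epsilon-amine and *displace* the
propionyl group, so, e.g., a lysine lactylation (+72.0211 Da) appears as a
net +15.9949 Da — numerically an "oxidation" — on a propionylated
candidate.  Distinct modification combinations can be exactly isobaric
(malonyl = propionyl + quinone; lactyl = carboxyethyl; pyruvoyl =
propionyl + the in-gel +13.9792 adduct).  The workflow treats these
identities as first-class objects: they are enumerable
(`chemistry.decompose_delta`), they shape the search (offsets displace
derivatization, so net shifts are computed automatically), and they are
adjudicated against fragment-level evidence at the end.

## Chemistry

Compositions are signed element→count maps over C, H, N, O, S, P and the
heavy isotopes 13C, 2H, 15N as distinct symbols, with monoisotopic masses
from pyteomics (NIST).  Modifications carry a name, a composition or an
explicit mass, residue/terminus targets, a category (biological,
chemical_artifact, derivatization), optional diagnostic neutral losses,
and a flag stating whether they block lysine derivatization.  Blocking
semantics follow epsilon-amine chemistry: every acylation and glycation
adduct blocks; mono-methylation does not (me1 + propionyl stack on one
lysine); di-/tri-methylation are treated as blocking.  Only the me0/me1
behaviour is chemically settled; the me2/me3 choice is a documented
package decision.

The in-gel +13.9792 Da adduct is stored as an explicit mass (its formal
composition O−H2 would give 13.9793) and does *not* block derivatization —
it is observed stacked on propionylated lysines, where the +70.0054 Da sum
mimics pyruvoyl.  For this reason pyruvoyl is excluded from the default
offset list of the pipeline's DMO step; it remains in the registry and
participates in decompositions.

Delta decomposition enumerates all multisets of ≤ `max_terms` registry
modifications within `tol` (default 1 mDa) of the delta, ordered by
|mass error|, then fewest terms, then lexicographic names — a
deterministic ordering chosen because no principled numeric ranking of
alternatives exists at the precursor level alone.

## Digestion and candidate space

C-side cleavage rules (ArgC-like: after R; trypsin: after K/R), with
missed cleavages, length bounds, and no proline suppression (histone
peptides of interest are short and arginine-terminated; the exception
rules would add branches without affecting them).  Initiator methionine
is removed on FASTA loading (opt-out flag) so positions match histone
nomenclature (H3K9, H4K77).  Decoys reverse the sequence holding the
C-terminal residue in place, preserving the cleavage pattern; entrapment
entries are flagged separately from decoys and are digested tryptically
without derivatization chemistry (the foreign-species proteome does not
pass through the histone preparation protocol).

Peptidoform slots (0 = N-terminus, 1..L residues, L+1 = C-terminus) hold
ordered *stacks* of modifications, because derivatization can co-occur
with a biological mark on one residue; at most one variable (searched)
modification is placed per slot.  Variable-modification enumeration is
deterministic (fewest modifications first) and capped (default 99 000
combinations) with a logged truncation warning.

Identical peptidoforms arising from several variants (every H3 variant
shares the N-terminal tail peptides) are merged into a single candidate
carrying all protein placements, so variants do not compete against each
other during search and localization ambiguity counts positions, not
duplicated database rows.

## Spectra and the synthetic-data generator

Fragments are b/y ions at charges 1–2 (a/c/x/z ions are out of scope),
with `mz = (neutral + z × 1.007276)/z`; the complementarity identity
`b_i + y_(L−i) = M` holds by construction.  Modifications declaring
diagnostic neutral losses contribute satellite ions for every fragment
containing the modified residue (CO2 for malonyl, H3PO4 for phospho).
Satellites are diagnostic evidence only and never enter the score.

The generator emulates calibrated DDA HCD data of derivatized histone
peptides.  Defaults, chosen once to mirror the study conditions the
workflow is designed for: per-fragment detection probability 0.9,
log-normal fragment intensities (ln-mean ln(1e5), σ 0.7), 20 uniform
noise peaks per spectrum at ~100× lower log-normal intensity, 3 ppm
Gaussian m/z jitter, precursor charges 2–3, 60% of target spectra
modified, a plan of 15 spiked (protein, position, modification) sites
drawn from 12 biological modification classes, 10% artifact rate
(S/T-propionylation and the in-gel adduct), 10% under-derivatized
tryptic peptides, and an optional random-sequence entrapment proteome of
which a configurable fraction is present in the search database
(default 1.0; entrapment experiments use 0.7 to emulate database
incompleteness).  Every spectrum carries its generating peptidoform as a
truth record.

What the generator does **not** emulate: chromatography and co-isolation
chimeras, intensity structure along the ion series, deamidation/pyro-Glu
chemistry, isotope-envelope peaks, charge-state misassignment, and real
homology between the entrapment species and the targets.  Passing tests
therefore demonstrate the correctness and calibration of the *workflow
logic* under realistic noise, not instrument-level performance on real
raw files.

## Searching and scoring

The score is `ln(Nb! · Ny! · ΣI_b · ΣI_y)` with factorials capped at 20!
and each intensity sum floored at 1; Nb/Ny count distinct matched
fragment numbers per series (charge states of one fragment count once).
Matching is greedy nearest-peak within a ppm tolerance (20 ppm default),
each peak used once, in deterministic ion order.  The score is the
package's own definition; no equivalence with any external engine is
claimed.  Ties break by fewer modifications, then lexicographic peptide,
then the modification string — fully deterministic.

Closed and DMO searches match precursors at 20/10 ppm respectively with
precursor isotope errors −1/0/+1/+2 (configurable); the open window
(−150/+500 Da default) subsumes isotope errors, so open mode allows
none.  Open-search candidates whose delta is within the ppm tolerance of
zero are scored exactly as in closed search, which makes
`open_search(window=(0,0))` and `dmo_search(offsets=())` reduce to
`closed_search` identically.  Delta localization tries the shift at every
residue and both termini plus "no position", rescoring shifted fragment
arrays; only the best few candidates by unshifted score (default 5) are
fully localized, a standard engine economy.  Unlocalized winners are kept
for the histogram but excluded from site reporting.

DMO offsets are registry modifications restricted to their target
residues; placing an offset on a lysine displaces derivatization when the
modification blocks the epsilon-amine, and the PSM reports the *net*
precursor shift together with the offset identity and position.  The
number of tied best positions for the same peptide and offset is reported
("Number Best Positions"); the quality filter requires it to be exactly 1.

A sorted-candidate binary search over neutral mass is the indexing
baseline (adequate at the package's scale); no fragment index is built.

## Validation

FDR groups: (1) unmodified, (2) chemical modifications only (including
derivatization), (3) ≥1 biological modification.  For entrapment
*reporting* a two-category convention applies, folding
chemically-modified-only peptides into "unmodified" — both conventions
are exposed because they serve different questions (score-distribution
heterogeneity vs biological-claim error).  q-values are
`#decoys ≥ s / #targets ≥ s` with tied scores pooled at one threshold,
monotone smoothing, and no +1 correction (documented; the package's
synthetic studies have ample decoys, where +1 mainly costs sensitivity).
Acceptance requires the PSM q-value and (by default) the peptidoform-level
q-value (best PSM per form) to pass.

Quality filters: ≥50% of theoretical b+y ions matched, and unambiguous
single-position localization for every mass offset.

Adjudication re-places every isobaric decomposition of an accepted
offset's mass on the same base peptide and rescores.  An alternative
wins only when it scores strictly higher *and* each additionally matched
peak is at least 3× the median intensity of peaks explained by neither
assignment (the noise estimate deliberately excludes both assignments'
matches; 3× is a package choice, as is the ≥2-satellite rule by which
declared diagnostic neutral losses override the comparison and keep the
original assignment).  PSMs whose offset mass has only the trivial
decomposition are never changed.

Entrapment error = 100 × (entrapment-origin spectra accepted as
biologically modified histone peptides) / (all spectra so accepted),
undefined at zero denominator.

## Pipeline choices

Artifact promotion from the open step: histogram bins (0.01 Da) covering
≥1% of nonzero-delta PSMs and annotatable as a single non-biological
registry modification are promoted — as *variable modifications*, not
offsets, so an artifact can co-occur with a biological offset on the same
peptide.  Protein abundance for the top-N database option is spectral
counting (intensity-based quantification is out of scope).  Histone
classification of database entries is pattern-based
(`proteolysis.HISTONE_PATTERNS`), not a fixed accession list.  All TSV
outputs and the JSON-lines audit log are byte-reproducible for a fixed
seed and configuration.

Problem sizes used by the test-suite studies: 150–500 spectra per run,
1000 spectra × 10 seeds for the two-species entrapment comparison, the
bundled four-protein histone panel plus 20 random-sequence entrapment
proteins — sizes at which every statistic the tests assert (recovery,
error rates, monotone step counts) is stable across seeds.

## Known limitations

- The bundled histone panel is compact (H3.1, H3.2, H3.3, H4); users
  supply their own FASTA for full variant coverage, and the H1
  no-priority reporting mode is exercised with synthetic variant
  fixtures.
- Single mass offset per peptide in DMO (artifacts enter as variable
  modifications instead); spectra carrying two biological offsets
  simultaneously are only reachable when the pair was planned on one
  candidate.
- No mixture-model posteriors, no mass recalibration, no retention-time
  or ion-mobility information, no semi-enzymatic digestion, no
  quantification, no DIA.
- The bundled registry is a static list covering the modification classes
  the workflow targets, not a Unimod mirror; extension is via YAML or
  `Registry.add`.
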