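# Methods

## Scope and model

`oligoxl` analyses chemical crosslinking of a homo-oligomeric ring protein
read out by MALDI-TOF peptide mass fingerprinting. The observable is a list
of singly-protonated monoisotopic masses per SDS-PAGE gel band (monomer,
oligomer, untreated control). The model of the experiment is:

* Trypsin cleaves C-terminal to Lys/Arg, not before Pro (configurable
  proline rule, default on). A crosslinker-modified lysine is chemically
  invisible to trypsin, so it is an *obligatory* missed cleavage and does
  not consume the missed-cleavage budget; the budget
  (`max_unmodified_missed`, default 1) applies to unmodified internal
  K/R only.
* Cysteines carry a fixed carbamidomethyl modification (+57.02146 Da) from
  iodoacetamide alkylation. Variable modifications are out of scope.
* A crosslink product is either a **loop-link** (both crosslinker ends in
  one peptide) or a **cross-link** (two peptides). A crosslinked lysine
  must be internal to its peptide: a K at a cleaved C-terminus was by
  definition unmodified. The single exception is the protein C-terminus,
  which is a chain end rather than a cut. The protein N-terminal α-amine
  is a first-class pseudo-site (`N`), distinct from residue positions.
* Site choices with identical mass are collapsed into one candidate with
  an explicit ambiguity set (rendered `190/193–200`); ambiguity is never
  silently resolved. Candidates within 0.001 Da are merged into one
  ledger entry listing all explanations.

## The DMS bridge mass

Textbook amidination chemistry predicts a bridge of C₈H₁₂N₂
(136.1000 Da) per formed DMS crosslink. Published MALDI assignment tables
for this chemistry, however, are reproduced exactly — to better than 1 mDa
across every row computable from printed peptide sequences — by a bridge of
**208.0534 Da**, the monoisotopic mass of C₈H₁₄N₂Cl₂, i.e. DMS
dihydrochloride minus two methanol leaving groups. This is the convention
of the classic assignment software used to produce such tables. Both
profiles ship (`dms`, the table-consistent default, and `dms-amidine`);
the bridge constant is a plain field of `CrosslinkerProfile` and can be
set freely. The geometric span is independent of this choice: arm 11 Å +
2 × 6.5 Å lysine side-chain reach = 24 Å Cα–Cα.

## Classification rules

Two rules of different logical strength decide intra- vs inter-subunit:

1. **Overlap rule** (deductive): a cross-link between peptides with
   intersecting residue intervals, or between two copies of the same
   peptide (self-pair), cannot arise within one chain. A *mass* is
   overlap-forced only when **every** candidate explanation of that mass
   is overlap-forced; a single non-overlapping isobaric explanation
   removes the forcing.
2. **Band-differential rule** (inferential): a mass matched in the
   monomer band is intra-subunit (evidence `band-monomer`); a mass
   matched only in oligomer bands is inter-subunit
   (evidence `band-differential`).

When the rules disagree — an overlap-forced mass observed in the monomer
band — the deductive rule wins: the verdict is `inter` with evidence
`overlap-forced` and a `monomer-band conflict` flag. Published monomer-band
tables do contain such rows; the package surfaces the contradiction
instead of guessing intent.

## Peak matching

Deviations are signed ppm, `(obs − theo)/theo × 1e6`, with a default
tolerance of 50 ppm. All candidates within tolerance are reported, ranked
by |ppm| and then by fewer total sites (simpler explanation first).
Candidates whose peptides span an excluded-observability position (e.g. a
heterogeneously glycosylated Asn) are suppressed unless explicitly
requested. Control subtraction is one-sided: sample peaks within tolerance
of any pooled control peak are removed. Replicate support counts the
number of spectra of one band containing a peak within tolerance of a
theoretical mass and reports the maximum-|ppm| deviation over those
spectra — the convention of published tables, which therefore differs from
the deviation of any single representative spectrum. Published table signs
are internally inconsistent, so only |ppm| magnitudes are compared in
tests.

## Distance validation

Structures are read from (optionally multi-model) PDB files; each MODEL is
treated as a trajectory frame, and only Cα coordinates are used. The ring
adjacency is computed from chain centroids by nearest-neighbour traversal
and validated (each chain's two cycle neighbours must be its two nearest
centroids); ambiguous geometry is an error that asks for an explicit
cycle. The orientation tag (`ccw`/`cw`) gives the circulation of the
cycle viewed down the ring axis from the N-terminal side; mirroring the
coordinates flips it.

For a site pair (i, j), intra distances are measured within every chain
and inter distances across every adjacent interface in both orientations
(i on a chain and j on its successor, and the reverse), over all frames.
Mean, min and max are reported. Satisfiability against the linker span
uses the **mean** by default, since trajectory-averaged distances are the
published convention; a `min` criterion is available because interfaces
vary and a link needs only one permissive geometry. An ambiguity set is
satisfiable if any member pair is. The N-terminal pseudo-site maps to the
first resolved residue's Cα with the same side-chain reach, as no α-amine
geometry is available. Solvent accessibility and steric occlusion are
deliberately not modelled; verdicts are purely distance-based.

## Synthetic experiments

The generator (`oligoxl.simulate`) emulates the observable surface of the
experiment, not its physics:

* **Geometry**: one random Cα walk (3.8 Å steps) confined to a globular
  volume whose radius scales as 2.5·n^⅓ Å, replicated by rotation about
  the z-axis onto a regular n-gon (default 5 subunits) of ring radius
  14 Å — adjacent subunits in contact, since interface proximity is what
  produces inter-subunit crosslinks. Traces satisfy no Ramachandran or
  excluded-volume constraints; only inter-site distances matter for the
  logic under test.
* **Sequence**: residues drawn per position (Lys density 0.10, Arg 0.05,
  otherwise uniform; no Pro), at least two lysines guaranteed.
* **Truth**: every amine pair within the 24 Å span — intra within a
  chain, inter across one adjacent interface (self-pairs included) — is
  eligible; a seeded fraction (default 0.6) forms. Each formed link's
  product mass is computed from the fully-cleaved peptides around its
  blocked sites.
* **Spectra**: monomer = intra masses + plain tryptic fingerprint;
  oligomer = all link masses + fingerprint; control = fingerprint only.
  Gaussian ppm noise (default σ = 10 ppm) and uniform decoy peaks
  (default 5 per spectrum, 500–4500 Da) are added. One seed threads
  through all stages; no global random state.

**Scoring is at the mass level.** The gel-band readout carries information
per mass, not per link: an inter-subunit link whose product mass is also
produced by a formed intra-subunit link appears in the monomer band
regardless, and no band-based method can recover its inter identity. A
truth mass is therefore labelled `intra` if any formed intra link produces
it, `inter` if only inter links do, and precision/recall compare call
verdicts against these labels. On a noiseless, decoy-free channel recovery
is exact unless distinct masses collide within the matching tolerance;
with 10 ppm noise and decoys, within-tolerance collisions are the only
loss mechanism, and mean inter-link precision and recall across seeds
stay above 0.9. Passing these tests demonstrates the correctness of the
enumeration/matching/classification logic — not robustness to the many
features of real spectra (isotope envelopes, adducts, intensity effects,
calibration drift) that the generator deliberately omits.

## Problem sizes and numerics

Default test problem sizes — 60-residue subunits, pentameric rings,
single-frame structures, 20-seed recovery sweeps — were chosen so the full
suite exercises every code path in seconds while keeping candidate ledgers
in the low hundreds of entries, comparable in density to a real tryptic
fingerprint. Ledger merging uses a fixed 0.001 Da window; matching windows
are computed on the observed mass with a guard factor so that tolerance is
always evaluated against the theoretical mass. Degenerate inputs (empty
peak lists, proteins without K/R, spans of zero, missing Cα records,
fewer than three chains) return empty results, recorded warnings, or
actionable errors as appropriate rather than crashing.

## Known limitations

* Dead-end (mono-link/hydrolysed) products are not enumerated; no
  published row requires them.
* Heterobifunctional or MS-cleavable crosslinkers, semi-tryptic peptides,
  variable modifications and MS/MS fragment evidence are out of scope.
* Crosslinks between non-adjacent subunits of the ring are not modelled.
* Band composition is taken from peak-list metadata; no molecular-weight
  estimation is attempted.
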