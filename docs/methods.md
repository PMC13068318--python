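# Methods

## The contact-based alignment model

A peptide–HLA class II complex is reduced to three polymer chains (α, β,
peptide). The method assumes that the groove-anchoring contact network of any
bound peptide resembles that of CLIP, the invariant-chain fragment that
occupies the groove of newly synthesized HLA II molecules. A CLIP-bound
*prototype* complex therefore serves as the template: its peptide is
renumbered 1..n, its chain residues keep their author numbering, and its
contact map defines (i) the anchor fingerprint — the partner set of the
most-contacted peptide position (URN 5 in both the DR and DQ grooves) — and
(ii) the reference set of contact triples against which *similar contacts*
(SC) are counted.

Aligning a target complex proceeds in five steps:

1. compute the target's peptide↔α/β contact map;
2. transfer prototype chain numbering to the target α and β chains by global
   sequence alignment;
3. find the target anchor: the peptide residue whose (role, chain position)
   partner set has maximal overlap with the prototype anchor fingerprint,
   accepted when the overlap is at least `overlap_min`;
4. renumber the whole peptide by offset so the anchor sits at URN 5
   (positions may run below 1 for long N-terminal flanks; they are kept, not
   clipped);
5. intersect the target triples with the prototype triples (SC) and validate:
   the numbering is accepted iff at least 9 core positions carry at least one
   SC and at least 50% of all core contacts are SC. The core is group
   specific (DR: URN 3–14, DQ: 4–14) and configurable.

Residue chemistry never enters steps 3–5; that is the point of the method —
the register is fixed by *where* contacts land, not by what residues make
them.

### Contact definition

The contact computation reproduces the "contact surface" semantics of
CSU-style interface analysis with a fully documented construction. Each heavy
atom carries a deterministic Fibonacci point set on its solvent-accessible
sphere (van der Waals radius + probe, probe 1.4 Å, 256 points/atom by
default). Points occluded by sibling atoms of the same residue are removed.
Every surviving point is attributed to its nearest atom outside the residue
and contributes its share of sphere area to that atom's residue when the
distance is within `r_partner + 2·probe`. The pair CSA is the mean of the two
one-sided areas; a contact is any pair with CSA above `csa_min` (default 0,
i.e. any positive area). A heavy-atom distance prefilter (default 6.5 Å)
accelerates the search and can be disabled for brute-force verification; the
spatial-index and all-pairs paths produce identical record sets.

Putative hydrogen bonds are flagged when any N/O/S heavy-atom pair across the
interface lies within 2.5–3.5 Å. No angle term is used because hydrogens are
absent from the inputs.

Because the original CSU parameterization is not published alongside the
method, `calibrate_csa_min` sweeps the acceptance threshold against reference
per-position contact counts (e.g. a prototype contact table) and reports the
error profile together with the chosen value.

### Chain numbering transfer

Needleman–Wunsch global alignment with BLOSUM62 and affine gaps (open 10,
extend 1), via Biopython's `PairwiseAligner`. Matched target residues inherit
prototype position numbers; the mapping is strictly increasing and unmatched
residues are explicit gaps. An identity floor (default 40%) turns a
misassigned chain into a hard error rather than a silent mis-numbering. The
defaults are conventional, not fitted; both are configurable.

### Chain-role assignment

The peptide is the shortest chain within a 9–30 residue window (CLIPs run
15–18, minimal cores 9); α and β are told apart by alignment score against
bundled reference chain sequences. Ties in either step raise an ambiguity
error that an explicit chain configuration resolves. The bundled reference
sequences are *synthetic stand-ins* (the file says so); real prototype chain
sequences can be passed in wherever the synthetic ones are used by default.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `probe` | 1.4 Å | solvent probe radius of the point surfaces |
| `points_per_atom` | 256 | Shrake–Rupley density; the test oracle uses 2560 |
| `csa_min` | 0 Å² | contact acceptance threshold; sweepable by calibration |
| `prefilter` | 6.5 Å | heavy-atom candidate-pair cutoff; `None` = all pairs |
| h-bond window | 2.5–3.5 Å | donor–acceptor heavy-atom distance |
| `overlap_min` | 0.6 | required fraction of the anchor fingerprint ("most") |
| identity floor | 0.4 | minimal chain identity vs the prototype |
| core range | DR 3–14, DQ 4–14 | positions entering the validity rule |
| gap scores | 10 / 1 | affine gap open/extend, BLOSUM62 |

The anchor criterion operationalizes "all or most of its contacts": 0.6 is
the package's reading of "most" and is deliberately exposed; when no residue
reaches it, the error carries the full ranked register list so alternative
peptide placements can still be compared.

## Property tables

* **Hydropathy grouping** — hydrophobic {A,V,L,I,M,F,W,Y,C,P} (+1), Gly
  neutral (0), the remaining nine residues hydrophilic (−1). Tyr counts as
  hydrophobic (large nonpolar face). The sets are overridable by
  configuration since reasonable conventions differ for Cys and Pro.
* **Hydropathy scales** — Kyte–Doolittle is built in; any scale loads from a
  two-column TSV and registers under a name.
* **Volumes** — Zamyatnin residue volumes. The five printed class intervals
  (60–90, 108–117, 138–154, 162–174, 189–228 Å³) contain all 20 residues, so
  class membership is fixed per residue at table construction and verified at
  import; the nearest-interval fallback exists but is never exercised by the
  standard table.
* **Flexibility** — hf {P,S,A,G,D}, mf {T,N,Q,K,E,R,V,C}, wf {I,L,M,F,Y,W,H};
  a deliberate first-approximation proxy with no context dependence.
* **CPS** — 0–100 scores for the 210 unordered residue pairs, classed strong
  (≥80), intermediate (40–79), weak (<40). The reference table is external
  (documented TSV schema); `CpsTable.uniform()` provides a synthetic constant
  table so tests exercise classification and averaging without the reference
  values.

## The synthetic fixture generator

Fixtures emulate exactly what the pipeline consumes: a two-chain groove with
a bound peptide whose residue–residue contacts are planted and known. The
peptide lies along the x axis (one Cα per residue, 10 Å apart); chain
backbones sit on walls 18 Å away; each planted triple places one side-chain
pseudo-atom of the named chain residue on a ring slot 4.55 Å from the partner
peptide Cα. The slot geometry guarantees that every planted pair has positive
CSA while every non-planted peptide/chain pair stays beyond the 7.7 Å
geometric reach of the contact construction — so contact recovery has exact
ground truth. A `half_plane` mode confines partners to z < 0, giving +z an
unambiguous "out of the groove" meaning for monotonicity experiments.
Capacity is 14 planted partners per peptide residue (7 in half-plane mode),
enough for the 13-partner anchor fingerprint. Files are byte-deterministic
per seed.

What fixtures do **not** emulate: real stereochemistry, rotamers, backbone
geometry, hydrogen-bond networks, or the crowded packing of a real groove.
Passing fixture tests therefore demonstrates the correctness of the contact
construction, anchor logic, numbering and bookkeeping — not the empirical
adequacy of the contact definition on crystal structures, which requires the
real prototype coordinates and the calibration sweep.

The toy prototype grooves plant the bundled unified DR/DQ SC triples at their
URN positions (83 contacts for DR over positions 3–14, 85 for DQ over 4–14;
anchor fingerprints of 9α+4β and 9α+3β respectively), so prototype-level
bookkeeping runs against the published contact architecture. Random target
fixtures re-index those triples to a random register (peptide length 12–18,
random sequence, 85% triple retention, 5% chain mutations) — the conditions
under which anchor recovery is reported.

## Numerical choices and degenerate inputs

* Point-surface areas are quantized at ~0.47 Å²/point at default density; the
  dense-grid oracle comparison is at 5% relative tolerance, and the two
  one-sided areas agree within the same band on symmetric cases.
* Anchor ties break by larger total contact count, then smaller residue
  index; prototype anchor ties break by α-chain count, then smaller position.
* Modified (non-standard) and unmodeled (coordinate-less) peptide residues
  are kept in the sequence, excluded from contact counting, reported in a
  skipped list, and their URN positions leave both the numerator and the
  denominator of the SC fraction.
* Altloc atoms: highest occupancy wins. Waters, ligands and hydrogens are
  discarded. Author numbering gaps become explicit unmodeled placeholders.
* Contacts with chain residues that fall outside the prototype numbering
  cannot be SC but still inflate the core denominator — an unfavourable but
  honest reading of the validity rule.
* Unified-map percentages are reported with both denominators (all
  structures, and structures modeling the position) because reference tables
  are ambiguous on this point.

## Known limitations

* The contact definition is a documented reconstruction, not the original
  CSU program; absolute CSA values on real structures should be read through
  the calibration sweep.
* Single binding register per structure; flanking-region statistics beyond
  reporting sub-core URN positions are out of scope, as are TCR interactions,
  biological-assembly reconstruction and the chemistry of post-translational
  modifications (flagged and excluded only).
* The bundled reference chain sequences are synthetic; role discrimination on
  real structures needs real prototype sequences supplied by the user.
* Descriptive frequencies only — no statistical testing across groups.
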