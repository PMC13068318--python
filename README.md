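# urnmap

Contact-based alignment of peptide–HLA class II complexes.

HLA class II molecules present extracellular peptides to CD4+ T cells from an
open-ended groove formed by an α and a β chain. Because the groove is open,
the same peptide can slide into several binding registers, which makes
sequence-based comparison of different peptide–HLA II structures ambiguous.
`urnmap` instead aligns complexes by their **contacts**: every structure is
put into a *Unified Residue Numbering* (URN) anchored at the peptide position
whose groove contacts best reproduce the contact fingerprint of CLIP — the
invariant-chain fragment that occupies every nascent HLA II groove and acts
as a generic, allele-independent "lid".

The core objects and operations:

* **Contact map** — every peptide↔α and peptide↔β residue pair with positive
  contact surface area (CSA, Å²), nearest heavy-atom distance, and a putative
  hydrogen-bond flag. CSA comes from Shrake–Rupley point surfaces
  (probe 1.4 Å, ≥240 points/atom) with nearest-partner attribution.
* **Anchor detection** — the prototype CLIP complex's high-contact position
  (URN 5) defines a partner set *P*; the target peptide residue *i*
  maximizing |partners(i) ∩ P| / |P| becomes the anchor if the overlap
  reaches `overlap_min` (default 0.6), and the peptide is renumbered by
  offset so the anchor sits at URN 5.
* **Similar contacts (SC)** — triples (peptide URN position, chain role,
  chain position) present in both the target and prototype maps, *regardless
  of residue chemistry on either side*.
* **Validation** — a URN is accepted iff ≥9 core positions (DR 3–14,
  DQ 4–14) carry ≥1 SC **and** ≥50% of all core contacts are SC.
* **Position profiles & aggregation** — per-position hydropathy (+1/−1/0),
  Kyte–Doolittle sums, Zamyatnin volumes in five classes, hf/mf/wf
  flexibility classes, contact-preference scores (CPS: strong 80–100,
  intermediate 40–79, weak 0–39), and unified contact maps with per-SC
  frequencies across structure groups.

A synthetic fixture generator builds valid three-chain PDB files whose
contacts are planted and exactly known, so the whole pipeline is testable
without downloading structures.

## Worked example

```python
import numpy as np
from urnmap import (PrototypeReference, align_complex, generate_toy_complex,
                    prototype_fixture_spec, random_register_spec)

toy = generate_toy_complex(prototype_fixture_spec("dr"))
proto = PrototypeReference.from_complex(toy.complex, "dr")
res = align_complex(generate_toy_complex(
    random_register_spec(np.random.default_rng(11))).complex, proto)
print(res.urn.anchor_index, res.anchor_overlap, res.validation.valid)
```

Running `python examples/01_align_toy_complex.py` prints:

```
prototype: 83 contacts, anchor at URN 5 with 13 partners
target peptide: DSLNPRALDKWM (planted anchor index 4)
found anchor index 4 (partner-set overlap 1.00) -> URN position 5
core positions with >=1 SC: 10 (need >=9)
SC fraction in core: 1.00 (need >=0.5)
URN accepted: True
```

The prototype groove carries 83 contacts over the DR core and its anchor
touches 13 chain residues (9 α + 4 β); the random target's planted anchor is
recovered exactly and the numbering validates. The other examples compute a
contact map with CSAs from a generated PDB file (`02`), the CLIP core profile
— total volume 1714.3 Å³, class counts 2/2/1/7/0, hydrophobicity count +2 —
(`03`), and the DR∩DQ unified-map comparison — 62 shared SC, 33 α + 29 β,
9 of them at the anchor position (`04`).

A thin CLI wraps the same functions: `urnmap contacts`, `urnmap align`,
`urnmap profile`, `urnmap aggregate`, `urnmap compare`, `urnmap fixtures`
(see `--help`).

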