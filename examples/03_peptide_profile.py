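"""Physicochemical profile of the CLIP core region.

Scores the DR-bound CLIP fragment (URN positions 3-14) position by position:
hydropathy group, residue volume and class, conformational-flexibility class,
plus the core-level summaries used as peptide-compatibility criteria.
"""

from urnmap import datasets
from urnmap.physchem import (flexibility_profile, hydrophobicity_count,
                             hydropathy_sum, position_profiles, profile_tsv,
                             volume_profile)

clip = datasets.clip_peptide("dr")
lo, hi = clip["core"]
core = clip["sequence"][lo - 1:hi]
print(f"CLIP (DR): {clip['sequence']}  core {lo}-{hi}: {core}\n")

print(profile_tsv(position_profiles({lo + i: aa for i, aa in enumerate(core)})))

vol = volume_profile(core)
flex = flexibility_profile(core)
print(f"total core volume: {vol.total} A^3")
print(f"volume classes: {vol.class_counts}")
print(f"hydrophobicity count (+1 hydrophobic / -1 hydrophilic / Gly 0): "
      f"{hydrophobicity_count(core):+d}")
print(f"Kyte-Doolittle sum: {hydropathy_sum(core):.2f}")
print(f"flexibility classes: {flex.counts}")
# The volume total and class counts constrain how the side chains fill the
# groove pockets; the signed hydrophobicity count and flexibility mix are the
# coarse compatibility criteria applied to candidate peptides.
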