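"""Composition and hydropathy of ligand positions vs natural backgrounds.

Compares specific and non-specific profile positions with a synthetic
disorderome (hydrophilic disordered regions cut into hexadecapeptides) and
with SLiM motif positions, using Roseman's Hydropathy Index (RHI; Gly = 0,
positive = hydrophobic). Optimal phage-derived ligands are expected to be
much more hydrophobic than disordered natural sequence, most of all at the
specific positions that contact the domain surface.
"""

import prmprofiler as pp

spec = pp.SyntheticSpec(seed=0)
peptides, _ = pp.gen_peptide_set(spec)
profile = pp.build_profile(peptides)

stats = pp.aggregate_position_stats([profile])
for cat in ("profile-specific", "profile-non-specific"):
    s = stats[cat]
    modal = max(s.aa_freq, key=s.aa_freq.get)
    print(f"{cat}: {s.n_positions} positions, mean RHI {s.mean_rhi:+.2f}, "
          f"top residue {modal} ({100 * s.aa_freq[modal]:.0f}%)")

regions = pp.gen_disorderome(spec, n_regions=400)
d = pp.disorderome_stats(regions)
print(f"disorderome: {d.n_positions} hexadecapeptide fragments, "
      f"mean RHI {d.mean_rhi:+.2f}, Trp at {100 * d.aa_freq['W']:.2f}%")

motifs = [
    pp.parse_elm_motif("P[TS]AP", "LIG_UEV", instances=["PTAP", "PSAP"]),
    pp.parse_elm_motif(".PPG.", "LIG_GYF", instances=["APPGF", "SPPGW"]),
]
slim = pp.slim_position_stats(motifs)
print(f"SLiM specific positions: mean RHI {slim['slim-specific'].mean_rhi:+.2f} "
      f"across {len(motifs)} motif classes (equal class weight)")
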