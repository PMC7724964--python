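"""Scan protein sequences with a finalized profile.

Plants the profile's consensus inside a background protein and scans a small
synthetic proteome. Each window's raw score sums the PWM weights of its
residues; the relative score divides by the best attainable score, so the
consensus window scores exactly 1.0.
"""

import numpy as np

import prmprofiler as pp

spec = pp.SyntheticSpec(seed=0)
peptides, _ = pp.gen_peptide_set(spec)
profile = pp.build_profile(peptides)
consensus = profile.consensus()

rng = np.random.default_rng(0)
bg = lambda n: "".join(rng.choice(list(pp.ALPHABET_20), n))
proteome = [
    ("PROT1", bg(40) + consensus + bg(40)),  # planted site at 41
    ("PROT2", bg(90)),
]

tables = pp.scan_proteome(proteome, profile, min_rel_score=0.7, top_k=5)
hits = tables[profile.prm_id]
print(f"profile {profile.prm_id}: {profile.n_positions} positions, "
      f"consensus {consensus}")
print(f"{len(hits)} hit(s) at relative score >= 0.7:")
for _, h in hits.iterrows():
    print(f"  {h.protein_id} {h.start}-{h.end}  rel={h.rel_score:.3f}")
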