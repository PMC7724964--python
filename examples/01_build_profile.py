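"""Build a specificity profile from phage-selected peptides.

Generates a synthetic peptide set from a planted Trp/Pro motif, runs the
clustering + gap-free alignment + weighted-PWM pipeline, and prints the
profile's key numbers. SP near 1 marks a position where essentially a single
residue is tolerated; SPt sums the significant positions, and a profile with
n >= 5 peptides and SPt > 1 counts as reliable.
"""

from pathlib import Path

import prmprofiler as pp

spec = pp.SyntheticSpec(seed=0)
peptides, truth = pp.gen_peptide_set(spec)
print(f"peptide set: {len(peptides)} peptides for {peptides.prm_id}")
print(f"planted consensus: {truth.planted.consensus()}")

profile = pp.build_profile(peptides)
print(f"aligned peptides: {profile.n_peptides} ({profile.n_outliers} outliers removed)")
print(f"profile length:   {profile.n_positions} positions, SPt = {profile.spt:.2f}")
print(f"consensus:        {profile.consensus()}")
n_spec = sum(c == "specific" for c in profile.classes)
print(f"classes:          {n_spec} specific, {len(profile.classes) - n_spec} non-specific")
print(f"reliable (n>=5, SPt>1): {bool(pp.profile_gate([profile]))}")

out = Path("scratch/example_profile")
out.mkdir(parents=True, exist_ok=True)
pp.write_profile(profile, out / "profile.json")
pp.write_meme(profile, out / "profile.meme")
pp.render_logo(profile, out / "logo.png")
print(f"profile JSON, MEME matrix and logo written to {out}/")
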