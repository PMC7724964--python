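"""Composition and hydropathy statistics for peptide ligands.

Three kinds of sequence sets are compared on the same footing:

* specific and non-specific positions of phage-derived specificity profiles,
* specific (non-wildcard) and wildcard positions of curated SLiM motifs, and
* hexadecapeptide fragments of the disordered proteome ("disorderome"),

using Roseman's Hydropathy Index (RHI), a water/octanol partition scale for
side chains corrected for the solvation effect of flanking peptide bonds.
Glycine, having no side chain, is the benchmark at 0; positive values are
hydrophobic, negative hydrophilic. The hydropathy of a residue-frequency
column is the frequency-weighted mean RHI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import ALPHABET_20
from .peptide_io import DisorderedRegion, ElmMotif
from .profile_builder import SpecificityProfile

#: Roseman (1988) side-chain hydropathies, octanol/water, corrected for
#: neighboring peptide-bond solvation (as tabulated in AAindex ROSM880102).
#: Units: kcal/mol transfer free energy; Gly fixed at 0.
ROSEMAN_RHI: dict[str, float] = {
    "A": 0.39, "R": -3.95, "N": -1.91, "D": -3.81, "C": 0.25,
    "Q": -1.30, "E": -2.91, "G": 0.00, "H": -0.64, "I": 1.82,
    "L": 1.82, "K": -2.77, "M": 0.96, "F": 2.27, "P": 0.99,
    "S": -1.24, "T": -1.00, "V": 1.30, "W": 2.13, "Y": 1.47,
}


@dataclass(frozen=True)
class HydropathyTable:
    """Residue -> hydropathy value; must cover all 20 residues with Gly at 0."""

    values: Mapping[str, float]

    def __post_init__(self):
        missing = set(ALPHABET_20) - set(self.values)
        if missing:
            raise ValueError(f"hydropathy table missing residues {sorted(missing)}")
        if self.values["G"] != 0.0:
            raise ValueError("Gly must have hydropathy 0 (no side chain)")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def roseman_table() -> HydropathyTable:
    return HydropathyTable(dict(ROSEMAN_RHI))


@dataclass
class PositionStats:
    """Pooled composition and hydropathy for one category of positions."""

    category: str
    aa_freq: dict[str, float]
    rhi_values: np.ndarray
    mean_rhi: float
    n_positions: int

    def __post_init__(self):
        total = sum(self.aa_freq.values())
        if self.n_positions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.category}: aa_freq sums to {total}, not 1")


def position_hydropathy(
    column_freqs: Mapping[str, float] | np.ndarray,
    table: HydropathyTable | None = None,
    alphabet: Sequence[str] | None = None,
) -> float:
    """Frequency-weighted hydropathy of one position: sum_i f_i * RHI_i."""
    table = table or roseman_table()
    if isinstance(column_freqs, Mapping):
        items = column_freqs.items()
    else:
        if alphabet is None:
            raise ValueError("alphabet required for array-valued frequencies")
        items = zip(alphabet, column_freqs)
    total = 0.0
    for residue, freq in items:
        if residue not in table.values:
            raise KeyError(f"residue {residue!r} missing from hydropathy table")
        total += float(freq) * table[residue]
    return total


def sequence_mean_rhi(sequence: str, table: HydropathyTable | None = None) -> float:
    table = table or roseman_table()
    return float(np.mean([table[c] for c in sequence]))


def _freqs_as_dict(profile: SpecificityProfile, j: int) -> dict[str, float]:
    col = {a: 0.0 for a in ALPHABET_20}
    for i, a in enumerate(profile.alphabet):
        col[a] = float(profile.f[i, j])
    return col


def _mean_stats(category: str, freq_vectors, rhi_values) -> PositionStats:
    n = len(freq_vectors)
    if n == 0:
        warnings.warn(f"no positions in category {category!r}")
        return PositionStats(category, {a: 0.0 for a in ALPHABET_20},
                             np.array([]), float("nan"), 0)
    mean = {a: float(np.mean([v[a] for v in freq_vectors])) for a in ALPHABET_20}
    rhi = np.asarray(rhi_values, dtype=float)
    return PositionStats(category, mean, rhi, float(rhi.mean()), n)


def aggregate_position_stats(
    profiles: Iterable[SpecificityProfile],
    sp_threshold: float = 0.33,
    table: HydropathyTable | None = None,
) -> dict[str, PositionStats]:
    """Pool profile positions by class and average their frequency columns.

    Every retained position of every profile counts once; the category mean
    frequency is the unweighted mean of the per-position frequency vectors,
    and the hydropathy distribution collects each position's weighted RHI.
    """
    table = table or roseman_table()
    pools = {"profile-specific": ([], []), "profile-non-specific": ([], [])}
    for p in profiles:
        if not p.finalized:
            raise ValueError(f"{p.prm_id}: profile not finalized")
        for j in range(p.n_positions):
            cat = (
                "profile-specific"
                if p.sp[j] >= sp_threshold
                else "profile-non-specific"
            )
            col = _freqs_as_dict(p, j)
            pools[cat][0].append(col)
            pools[cat][1].append(position_hydropathy(col, table))
    return {cat: _mean_stats(cat, fv, rv) for cat, (fv, rv) in pools.items()}


def fragment_disorderome(
    regions: Iterable[DisorderedRegion],
    window: int = 16,
    step: int = 16,
    table: HydropathyTable | None = None,
) -> pd.DataFrame:
    """Cut disordered regions into fixed-length fragments and score each.

    Default: non-overlapping hexadecapeptides (window = step = 16), trailing
    remainders dropped. Returns a frame with one row per fragment and its
    mean residue RHI.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    table = table or roseman_table()
    rows = []
    for region in regions:
        L = len(region.sequence)
        for off in range(0, L - window + 1, step):
            frag = region.sequence[off : off + window]
            rows.append(
                {
                    "protein_id": region.protein_id,
                    "start": region.start + off,
                    "end": region.start + off + window - 1,
                    "sequence": frag,
                    "mean_rhi": sequence_mean_rhi(frag, table),
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "start", "end", "sequence", "mean_rhi"])


def disorderome_stats(
    regions: Iterable[DisorderedRegion],
    window: int = 16,
    step: int = 16,
    table: HydropathyTable | None = None,
) -> PositionStats:
    """Composition over all disorderome residues + per-fragment RHI distribution."""
    table = table or roseman_table()
    regions = list(regions)
    counts = {a: 0 for a in ALPHABET_20}
    total = 0
    for r in regions:
        for c in r.sequence:
            if c in counts:
                counts[c] += 1
                total += 1
    frags = fragment_disorderome(regions, window=window, step=step, table=table)
    aa_freq = {a: (counts[a] / total if total else 0.0) for a in ALPHABET_20}
    rhi = frags["mean_rhi"].to_numpy()
    return PositionStats(
        "disorderome", aa_freq, rhi,
        float(rhi.mean()) if len(rhi) else float("nan"), len(rhi),
    )


def slim_position_stats(
    motifs: Iterable[ElmMotif],
    table: HydropathyTable | None = None,
) -> dict[str, PositionStats]:
    """Per-position stats for SLiM motifs, averaged with equal class weight.

    Within each motif class, residue frequencies are computed per position
    from the aligned instances and positions are split by the wildcard rule
    (``.`` = non-specific, everything else specific). Class-level means are
    then averaged across classes so classes with many annotated instances do
    not dominate.
    """
    table = table or roseman_table()
    per_class = {"slim-specific": ([], []), "slim-non-specific": ([], [])}
    for motif in motifs:
        instances = []
        for inst in motif.instances:
            if motif.matches(inst):
                instances.append(inst)
            else:
                warnings.warn(
                    f"{motif.class_id}: instance {inst!r} does not match pattern; excluded"
                )
        if not instances:
            continue
        class_pools = {"slim-specific": ([], []), "slim-non-specific": ([], [])}
        for j, pclass in enumerate(motif.position_classes):
            col = {a: 0.0 for a in ALPHABET_20}
            seen = 0
            for inst in instances:
                if inst[j] in col:
                    col[inst[j]] += 1.0
                    seen += 1
            if seen == 0:
                continue
            col = {a: v / seen for a, v in col.items()}
            cat = "slim-specific" if pclass == "specific" else "slim-non-specific"
            class_pools[cat][0].append(col)
            class_pools[cat][1].append(position_hydropathy(col, table))
        for cat, (fv, rv) in class_pools.items():
            if fv:
                per_class[cat][0].append(
                    {a: float(np.mean([v[a] for v in fv])) for a in ALPHABET_20}
                )
                per_class[cat][1].append(float(np.mean(rv)))
    return {cat: _mean_stats(cat, fv, rv) for cat, (fv, rv) in per_class.items()}
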