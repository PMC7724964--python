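"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

* peptide sets drawn from a planted position-specific frequency model, placed
  at a random offset inside a 16-residue randomized region over a 19-letter
  alphabet (no Cys), with a configurable fraction of outlier peptides drawn
  entirely from the background — mimicking clones that bind a different site;
* disordered regions with a hydrophilic residue composition (Trp at 0.4%),
  matching the character of a predicted disorderome;
* toy two-chain PRM-peptide complexes with a planted interface: contacting
  side chains placed 4.0-4.9 A apart and everything else beyond 6 A, with
  glycine positions exercising the C-alpha surrogate rule.

One global seed drives independent per-generator substreams, so adding a
generator never perturbs fixtures produced by another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .alphabet import ALPHABET_20, ALPHABET_NO_CYS
from .peptide_io import DisorderedRegion, PeptideRecord, PeptideSet

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Hydrophilic, disorder-like residue composition; Trp pinned at 0.004.
#: Disorder-promoting residues (P, E, S, K, G, Q) dominate; aromatics and
#: aliphatics are rare, as in predicted disordered regions of the proteome.
DEFAULT_DISORDER_COMPOSITION: dict[str, float] = {
    "A": 0.080, "R": 0.058, "N": 0.040, "D": 0.058, "C": 0.010,
    "Q": 0.060, "E": 0.100, "G": 0.080, "H": 0.020, "I": 0.030,
    "L": 0.055, "K": 0.070, "M": 0.015, "F": 0.020, "P": 0.100,
    "S": 0.100, "T": 0.060, "V": 0.035, "W": 0.004, "Y": 0.005,
}


def _normalize(freqs: Mapping[str, float]) -> dict[str, float]:
    total = sum(freqs.values())
    return {a: v / total for a, v in freqs.items()}


@dataclass(frozen=True)
class PlantedProfile:
    """Per-position residue frequency vectors with designated specific positions."""

    positions: tuple[dict, ...]
    specific: frozenset[int]

    def __post_init__(self):
        for j, p in enumerate(self.positions):
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"position {j}: frequencies sum to {sum(p.values())}")

    def __len__(self) -> int:
        return len(self.positions)

    def modal_residue(self, j: int) -> str:
        return max(self.positions[j], key=self.positions[j].get)

    def consensus(self) -> str:
        return "".join(self.modal_residue(j) for j in range(len(self)))


def default_planted_profile() -> PlantedProfile:
    """A 6-position Trp/Pro-rich planted motif typical of PRM ligands.

    Five positions carry a strongly preferred residue (the kind of column a
    specific position shows); position 1 is indifferent (background).
    """
    bg = {a: 1.0 / len(ALPHABET_NO_CYS) for a in ALPHABET_NO_CYS}

    def spiked(residue: str, p: float, minor: dict | None = None) -> dict:
        rest = dict(minor or {})
        others = [a for a in ALPHABET_NO_CYS if a != residue and a not in rest]
        leftover = 1.0 - p - sum(rest.values())
        col = {a: leftover / len(others) for a in others}
        col[residue] = p
        col.update(rest)
        return _normalize(col)

    positions = (
        spiked("W", 0.90),
        dict(bg),
        spiked("P", 0.90),
        spiked("T", 0.85, {"S": 0.08}),
        spiked("A", 0.80, {"G": 0.08, "S": 0.05}),
        spiked("P", 0.90),
    )
    return PlantedProfile(positions=positions, specific=frozenset({0, 2, 3, 4, 5}))


@dataclass(frozen=True)
class ComplexGeometry:
    """Planted interface of a toy two-chain complex.

    ``contacts`` are (PRM residue, peptide residue) 0-based pairs; each
    peptide residue may appear in at most one contact (one side chain cannot
    sit next to two PRM residues 10 A apart). ``gly_positions`` force Gly at
    those peptide positions so the C-alpha surrogate rule is exercised.
    """

    prm_length: int = 40
    peptide_length: int = 8
    contacts: tuple[tuple[int, int], ...] = ((5, 2), (12, 4), (20, 6))
    gly_positions: tuple[int, ...] = (4,)
    noise: float = 0.05  # per-axis coordinate jitter, A


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything that controls fixture generation, reproducibly."""

    seed: int = 0
    planted_profile: PlantedProfile = field(default_factory=default_planted_profile)
    n_peptides: int = 50
    peptide_length: int = 16
    offset_range: int = 3
    outlier_fraction: float = 0.05
    disorder_composition: Mapping[str, float] | None = None
    complex_geometry: ComplexGeometry = field(default_factory=ComplexGeometry)
    prm_id: str = "SYN1"
    prm_family: str = "synthetic"

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class PeptideGroundTruth:
    """What the generator planted: core positions and outlier labels."""

    core_starts: tuple[int, ...]  # -1 for outliers
    outlier_flags: tuple[bool, ...]
    planted: PlantedProfile


def _sample(rng, freqs: Mapping[str, float]) -> str:
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters])
    return letters[rng.choice(len(letters), p=probs / probs.sum())]


def gen_peptide_set(spec: SyntheticSpec) -> tuple[PeptideSet, PeptideGroundTruth]:
    """Generate one PRM's peptide set from the planted profile.

    Each inlier peptide is a background left flank, a core sampled from the
    planted per-position frequencies, and a background right flank, with the
    core start jittered by up to ``offset_range`` positions around the
    center. Outliers are sampled entirely from the background.
    """
    rng = spec.rng(0)
    m = len(spec.planted_profile)
    L = spec.peptide_length
    if m > L:
        raise ValueError(f"planted profile ({m}) longer than peptide ({L})")
    bg = {a: 1.0 / len(ALPHABET_NO_CYS) for a in ALPHABET_NO_CYS}
    n = spec.n_peptides
    n_out = int(round(spec.outlier_fraction * n))
    outlier_idx = set(rng.choice(n, size=n_out, replace=False).tolist()) if n_out else set()
    center = (L - m) // 2

    records, starts, flags = [], [], []
    for p in range(n):
        if p in outlier_idx:
            seq = "".join(_sample(rng, bg) for _ in range(L))
            starts.append(-1)
            flags.append(True)
        else:
            off = int(rng.integers(-spec.offset_range, spec.offset_range + 1))
            start = min(max(center + off, 0), L - m)
            core = "".join(
                _sample(rng, spec.planted_profile.positions[j]) for j in range(m)
            )
            left = "".join(_sample(rng, bg) for _ in range(start))
            right = "".join(_sample(rng, bg) for _ in range(L - m - start))
            seq = left + core + right
            starts.append(start)
            flags.append(False)
        records.append(PeptideRecord(sequence=seq, prm_id=spec.prm_id, source="synthetic"))
    ps = PeptideSet(prm_id=spec.prm_id, prm_family=spec.prm_family, records=records)
    return ps, PeptideGroundTruth(tuple(starts), tuple(flags), spec.planted_profile)


def gen_disorderome(
    spec: SyntheticSpec,
    n_regions: int = 200,
    length_range: tuple[int, int] = (20, 120),
) -> list[DisorderedRegion]:
    """Generate disordered regions i.i.d. from the hydrophilic composition."""
    rng = spec.rng(1)
    comp = _normalize(dict(spec.disorder_composition or DEFAULT_DISORDER_COMPOSITION))
    letters = sorted(comp)
    probs = np.array([comp[a] for a in letters])
    regions = []
    for r in range(n_regions):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(letters[i] for i in rng.choice(len(letters), size=L, p=probs))
        regions.append(DisorderedRegion(f"IDR{r + 1:05d}", 1, L, seq))
    return regions


@dataclass(frozen=True)
class ToyComplex:
    """A generated two-chain complex and its planted ground truth."""

    pdb_string: str
    contacts: frozenset[tuple[int, int]]
    prm_sequence: str
    peptide_sequence: str
    prm_chain: str = "A"
    peptide_chain: str = "B"


def gen_toy_complex(spec: SyntheticSpec) -> ToyComplex:
    """Build a mock PRM-peptide complex with a known contact map.

    Residues sit on two widely separated rails (16 A apart, 10 A spacing
    along each), and each planted contact pulls one peptide side chain to
    4.0-4.9 A from its PRM partner's side chain; every non-planted residue
    pair stays beyond 6 A. Peptide positions listed in ``gly_positions`` are
    glycines, whose C-alpha stands in for the missing side chain.
    """
    geom = spec.complex_geometry
    rng = spec.rng(2)
    if not 5 <= geom.peptide_length <= 30:
        raise ValueError("peptide chain must have 5-30 residues")
    pep_used = [j for _, j in geom.contacts]
    if len(set(pep_used)) != len(pep_used):
        raise ValueError("infeasible geometry: peptide residue in multiple contacts")
    for i, j in geom.contacts:
        if not (0 <= i < geom.prm_length and 0 <= j < geom.peptide_length):
            raise ValueError(f"infeasible geometry: contact ({i},{j}) out of range")

    bg = [a for a in ALPHABET_20 if a not in "GC"]
    prm_seq = "".join(bg[i] for i in rng.choice(len(bg), size=geom.prm_length))
    pep = [bg[i] for i in rng.choice(len(bg), size=geom.peptide_length)]
    for g in geom.gly_positions:
        pep[g] = "G"
    pep_seq = "".join(pep)

    contact_of = {j: i for i, j in geom.contacts}

    def jitter():
        return rng.uniform(-geom.noise, geom.noise, size=3)

    st = gemmi.Structure()
    st.name = "SYNTH"
    model = gemmi.Model("1")

    def add_residue(chain, name, seqid, base_xyz, with_side_chain, side_xyz=None):
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(seqid, " ")
        x, y, z = base_xyz
        for aname, dx, dy in (("N", -1.2, 0.0), ("CA", 0.0, 0.0), ("C", 1.2, 0.0), ("O", 1.8, 1.0)):
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element("N" if aname == "N" else ("O" if aname == "O" else "C"))
            j = jitter()
            atom.pos = gemmi.Position(x + dx + j[0], y + dy + j[1], z + j[2])
            atom.occ = 1.0
            res.add_atom(atom)
        if with_side_chain:
            atom = gemmi.Atom()
            atom.name = "CB"
            atom.element = gemmi.Element("C")
            sx, sy, sz = side_xyz
            j = jitter()
            atom.pos = gemmi.Position(sx + j[0], sy + j[1], sz + j[2])
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)

    chain_a = gemmi.Chain("A")
    for i, aa in enumerate(prm_seq):
        add_residue(
            chain_a, _AA3[aa], i + 1,
            base_xyz=(10.0 * i, 0.0, 0.0),
            with_side_chain=True,
            side_xyz=(10.0 * i, 2.0, 0.0),
        )
    chain_b = gemmi.Chain("B")
    for j_res, aa in enumerate(pep_seq):
        if j_res in contact_of:
            i = contact_of[j_res]
            d = rng.uniform(4.2, 4.7)  # planted side-chain distance
            anchor_x, anchor_y = 10.0 * i, 2.0 + d
        else:
            anchor_x, anchor_y = 10.0 * j_res, 18.0
        if aa == "G":
            # no side chain: the planted distance applies to the C-alpha
            add_residue(chain_b, "GLY", j_res + 1,
                        base_xyz=(anchor_x, anchor_y, 0.0), with_side_chain=False)
        else:
            add_residue(chain_b, _AA3[aa], j_res + 1,
                        base_xyz=(anchor_x, anchor_y + 1.5, 0.0),
                        with_side_chain=True,
                        side_xyz=(anchor_x, anchor_y, 0.0))
    model.add_chain(chain_a)
    model.add_chain(chain_b)
    st.add_model(model)
    st.setup_entities()
    return ToyComplex(
        pdb_string=st.make_pdb_string(),
        contacts=frozenset((i, j) for i, j in geom.contacts),
        prm_sequence=prm_seq,
        peptide_sequence=pep_seq,
    )
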