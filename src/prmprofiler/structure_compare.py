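"""Compare phage-derived peptides with PRM-ligand complex structures.

Given complex structures (PDB/mmCIF) and the phage-selected peptides for a
query PRM, this module extracts (PRM chain, 5-30-residue peptide chain)
pairs, maps the binding interface (side-chain atoms within 5 A of the partner
chain), aligns the structure peptide against each phage peptide without gaps,
and scores physicochemical similarity using nine residue groups: aromatic
(WFYH), large polar/basic (NQKRH), large polar/acidic (NQDE), small polar
(NST), large hydrophobic (VILMF), small hydrophobic (ATVI), and G, P, C each
unique. Two residues are similar when they share at least one group.

Post-translationally modified residues are mapped to their parent residue for
sequence extraction but excluded from similarity arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
from Bio import Align

from .alphabet import STANDARD_RESIDUES
from .errors import FormatError
from .profile_builder import SpecificityProfile

#: The nine physicochemical residue groups used for similarity.
SIMILARITY_GROUPS: dict[str, frozenset[str]] = {
    "aromatic": frozenset("WFYH"),
    "large polar and basic": frozenset("NQKRH"),
    "large polar and acidic": frozenset("NQDE"),
    "small polar": frozenset("NST"),
    "large hydrophobic": frozenset("VILMF"),
    "small hydrophobic": frozenset("ATVI"),
    "glycine": frozenset("G"),
    "proline": frozenset("P"),
    "cysteine": frozenset("C"),
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})
_STANDARD_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


def similar(a: str, b: str, groups: Mapping[str, frozenset[str]] | None = None) -> bool:
    """True if the two residues share at least one physicochemical group."""
    if a == b:
        return True
    groups = groups or SIMILARITY_GROUPS
    return any(a in g and b in g for g in groups.values())


@dataclass
class StructurePair:
    """One PRM-ligand complex paired with a query PRM and its phage peptides."""

    pdb_id: str
    prm_chain: str
    peptide_chain: str
    prm_seq: str
    peptide_seq: str
    ptm_positions: frozenset[int] = frozenset()  # 0-based indices in peptide_seq
    prm_ptm_positions: frozenset[int] = frozenset()
    contacts: frozenset[tuple[int, int]] = frozenset()  # (prm idx, peptide idx), 0-based
    query_prm_id: str = ""
    matched_phage_peptide: str = ""
    scores: dict = field(default_factory=dict)
    structure: object = None  # gemmi.Structure, when loaded from coordinates

    def __post_init__(self):
        if not 5 <= len(self.peptide_seq) <= 30:
            raise ValueError(
                f"peptide chain must have 5-30 residues, got {len(self.peptide_seq)}"
            )
        for i, j in self.contacts:
            if not (0 <= i < len(self.prm_seq) and 0 <= j < len(self.peptide_seq)):
                raise ValueError(f"contact ({i},{j}) references missing residues")


@dataclass(frozen=True)
class PeptideAlignment:
    """Best ungapped register of a phage peptide on a structure peptide.

    ``offset`` maps structure-peptide index *s* to phage-peptide index
    ``s - offset``; ``span`` is the overlapping structure-peptide index range
    (start, stop).
    """

    offset: int
    similarity: float
    span: tuple[int, int]


# --- structure parsing -------------------------------------------------------

def _load_structure(source) -> gemmi.Structure:
    if isinstance(source, gemmi.Structure):
        return source
    text = None
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError, FileNotFoundError) as e:
            raise FormatError(f"cannot parse structure file {path}: {e}") from e
    else:
        text = str(source)
        try:
            st = gemmi.read_pdb_string(text)
        except (RuntimeError, ValueError) as e:
            raise FormatError(f"cannot parse PDB content: {e}") from e
    st.setup_entities()
    st.remove_ligands_and_waters()
    return st


def _chain_residues(chain: gemmi.Chain) -> list[gemmi.Residue]:
    residues = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if res.name == "HOH" or (info is not None and not info.is_amino_acid()):
            continue
        residues.append(res)
    return residues


def _residue_letter(res: gemmi.Residue) -> tuple[str, bool]:
    """One-letter code and PTM flag, mapping modified residues to parents."""
    if res.name in _STANDARD_RESNAMES:
        return gemmi.find_tabulated_residue(res.name).one_letter_code.upper(), False
    info = gemmi.find_tabulated_residue(res.name)
    letter = info.one_letter_code.upper() if info is not None else "X"
    if letter not in STANDARD_RESIDUES:
        letter = "X"
    return letter, True


def _chain_sequence(residues: list[gemmi.Residue]) -> tuple[str, frozenset[int]]:
    letters, ptms = [], set()
    for i, res in enumerate(residues):
        letter, is_ptm = _residue_letter(res)
        letters.append(letter)
        if is_ptm:
            ptms.add(i)
    return "".join(letters), frozenset(ptms)


def _identity_percent(query: str, target: str) -> float:
    """Local-alignment identity of target vs query, % of the shorter sequence."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    if not query or not target:
        return 0.0
    score = aligner.score(query, target)
    return 100.0 * score / min(len(query), len(target))


def extract_candidate_pairs(
    source,
    query_prm_seq: str,
    query_prm_id: str = "",
    peptide_range: tuple[int, int] = (5, 30),
    min_prm_identity: float = 10.0,
) -> list[StructurePair]:
    """Emit every (PRM-like chain, short peptide chain) pairing in a structure.

    A chain is a peptide candidate when its polymer length is within
    ``peptide_range``; a chain is PRM-like when it is longer than the peptide
    band and its local-alignment identity to the query PRM sequence exceeds
    ``min_prm_identity`` percent. Modified residues are mapped to their parent
    one-letter code and recorded as PTM positions; waters and non-polymer
    heteroatoms are ignored.
    """
    st = _load_structure(source)
    if len(st) == 0:
        raise FormatError("structure contains no models")
    model = st[0]
    if not any(_chain_residues(chain) for chain in model):
        raise FormatError("structure contains no polymer (amino-acid) chains")
    lo, hi = peptide_range
    peptide_chains, prm_chains = [], []
    for chain in model:
        residues = _chain_residues(chain)
        if not residues:
            continue
        seq, ptms = _chain_sequence(residues)
        if lo <= len(seq) <= hi:
            peptide_chains.append((chain.name, seq, ptms))
        elif len(seq) > hi:
            if _identity_percent(query_prm_seq, seq) > min_prm_identity:
                prm_chains.append((chain.name, seq, ptms))
    pairs = []
    for prm_name, prm_seq, prm_ptms in prm_chains:
        for pep_name, pep_seq, pep_ptms in peptide_chains:
            pairs.append(
                StructurePair(
                    pdb_id=st.name or "",
                    prm_chain=prm_name,
                    peptide_chain=pep_name,
                    prm_seq=prm_seq,
                    peptide_seq=pep_seq,
                    ptm_positions=pep_ptms,
                    prm_ptm_positions=prm_ptms,
                    query_prm_id=query_prm_id,
                    structure=st,
                )
            )
    return pairs


# --- contacts ----------------------------------------------------------------

def _side_chain_positions(res: gemmi.Residue) -> list[gemmi.Position]:
    """Side-chain atom positions; highest-occupancy altloc per atom name.

    Residues without side-chain atoms (Gly, or missing density) fall back to
    the C-alpha position as a surrogate so real interface residues are not
    silently dropped.
    """
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        if atom.is_hydrogen():
            continue
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            by_name[atom.name] = atom
    side = [a.pos for name, a in by_name.items() if name not in _BACKBONE_ATOMS]
    if side:
        return side
    ca = by_name.get("CA")
    return [ca.pos] if ca is not None else []


def contact_map(
    pair: StructurePair, cutoff: float = 5.0
) -> frozenset[tuple[int, int]]:
    """Interface residue pairs: minimum side-chain atom distance <= cutoff (A).

    The cutoff is inclusive. The result is stored on ``pair.contacts`` and
    returned; indices are 0-based into the chains' polymer sequences.
    """
    if pair.structure is None:
        raise ValueError("pair has no coordinates attached")
    model = pair.structure[0]
    prm_res = _chain_residues(model[pair.prm_chain])
    pep_res = _chain_residues(model[pair.peptide_chain])
    if not prm_res or not pep_res:
        raise ValueError("chain with no coordinates")
    prm_atoms = [_side_chain_positions(r) for r in prm_res]
    pep_atoms = [_side_chain_positions(r) for r in pep_res]
    contacts = set()
    for i, apos in enumerate(prm_atoms):
        for j, bpos in enumerate(pep_atoms):
            if any(a.dist(b) <= cutoff for a in apos for b in bpos):
                contacts.add((i, j))
    pair.contacts = frozenset(contacts)
    return pair.contacts


# --- sequence comparison -----------------------------------------------------

def percent_similarity(
    pep_a: str,
    pep_b: str,
    groups: Mapping[str, frozenset[str]] | None = None,
    mask: Iterable[int] | None = None,
    ptm_positions: Iterable[int] = (),
) -> float | None:
    """Percent of compared positions whose residues share a similarity group.

    The peptides must already be on a common register (equal length). ``mask``
    restricts the comparison to a position subset; PTM positions are excluded.
    Returns None when no position remains comparable.
    """
    if len(pep_a) != len(pep_b):
        raise ValueError("peptides must be on a common register (equal length)")
    positions = set(range(len(pep_a))) if mask is None else set(mask)
    positions -= set(ptm_positions)
    positions = {p for p in positions if 0 <= p < len(pep_a)}
    if not positions:
        return None
    hits = sum(1 for p in positions if similar(pep_a[p], pep_b[p], groups))
    return 100.0 * hits / len(positions)


def percent_identity(
    seq_a: str, seq_b: str, mask: Iterable[int] | None = None
) -> float | None:
    """Percent identical positions between two pre-aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be pre-aligned (equal length)")
    positions = range(len(seq_a)) if mask is None else [p for p in mask if 0 <= p < len(seq_a)]
    positions = list(positions)
    if not positions:
        return None
    hits = sum(1 for p in positions if seq_a[p] == seq_b[p])
    return 100.0 * hits / len(positions)


def align_peptides(
    structure_pep: str,
    phage_pep: str,
    groups: Mapping[str, frozenset[str]] | None = None,
    ptm_positions: Iterable[int] = (),
    min_overlap: int = 3,
) -> PeptideAlignment | None:
    """Slide the phage peptide along the structure peptide without gaps.

    Every register with at least ``min_overlap`` overlapping residues is
    scored by percent similarity (PTM positions of the structure peptide
    excluded); the best register wins, ties resolved toward the smallest
    absolute offset, then the leftmost. Returns None when no register has
    enough overlap.
    """
    if len(structure_pep) < 3 or len(phage_pep) < 3:
        raise ValueError("both peptides must have at least 3 residues")
    ptms = set(ptm_positions)
    best = None
    for offset in range(-(len(phage_pep) - min_overlap), len(structure_pep) - min_overlap + 1):
        s_start = max(0, offset)
        s_stop = min(len(structure_pep), len(phage_pep) + offset)
        if s_stop - s_start < min_overlap:
            continue
        a = structure_pep[s_start:s_stop]
        b = phage_pep[s_start - offset : s_stop - offset]
        local_ptms = {p - s_start for p in ptms if s_start <= p < s_stop}
        sim = percent_similarity(a, b, groups, ptm_positions=local_ptms)
        if sim is None:
            continue
        key = (-sim, abs(offset), offset)
        if best is None or key < best[0]:
            best = (key, PeptideAlignment(offset, sim, (s_start, s_stop)))
    return best[1] if best else None


def select_best_match(
    candidates: Iterable[StructurePair], min_prm_identity: float = 10.0
) -> StructurePair | None:
    """Pick the best-matched complex: highest peptide similarity, then PRM identity.

    Candidates whose full PRM identity is at or below ``min_prm_identity``
    percent are excluded; ties in peptide similarity break by interface
    identity, then full identity, then lexicographic PDB id. Returns None when
    nothing clears the identity floor.
    """
    def key(pair: StructurePair):
        s = pair.scores
        return (
            -(s.get("peptide_similarity") or 0.0),
            -(s.get("interface_identity") or 0.0),
            -(s.get("full_identity") or 0.0),
            pair.pdb_id,
            pair.prm_chain,
            pair.peptide_chain,
        )

    eligible = [
        c
        for c in candidates
        if (c.scores.get("full_identity") or 0.0) > min_prm_identity
    ]
    if not eligible:
        return None
    return min(eligible, key=key)


# --- orchestration -----------------------------------------------------------

def peptide_position_classes(
    profile: SpecificityProfile, sequence: str
) -> list[str | None]:
    """Per-residue specific/non-specific label for one aligned peptide.

    The peptide must be a row of the profile's alignment; residues outside the
    retained (trimmed) window get None.
    """
    if profile.alignment is None:
        raise ValueError("profile has no alignment attached")
    for row in profile.alignment.rows:
        if row.strip("-") == sequence:
            start = len(row) - len(row.lstrip("-"))
            lo, hi = profile.trim
            labels: list[str | None] = []
            for i in range(len(sequence)):
                col = start + i
                if lo <= col < hi:
                    labels.append(profile.classes[col - lo])
                else:
                    labels.append(None)
            return labels
    raise ValueError(f"{sequence!r} is not a row of the profile alignment")


def score_candidate(
    pair: StructurePair,
    phage_peptides: Sequence[str],
    query_prm_seq: str,
    cutoff: float = 5.0,
    profile: SpecificityProfile | None = None,
) -> StructurePair:
    """Fill a candidate's scores: PRM identities and best peptide similarity.

    The comparison span follows the availability of a specificity profile:
    with a profile, only the region of the phage peptide that aligns with the
    logo is compared; without one, only the structure-peptide residues in
    contact with the PRM.
    """
    if pair.structure is not None and not pair.contacts:
        contact_map(pair, cutoff=cutoff)
    # PRM identity: best ungapped register of query on the structure PRM
    reg = align_registers_identity(query_prm_seq, pair.prm_seq)
    pair.scores["full_identity"] = reg[1] if reg else 0.0
    interface_prm = sorted({i for i, _ in pair.contacts})
    if reg and interface_prm:
        offset = reg[0]
        mask = [
            i
            for i in interface_prm
            if 0 <= i - offset < len(query_prm_seq)
        ]
        a = "".join(pair.prm_seq[i] for i in mask)
        b = "".join(query_prm_seq[i - offset] for i in mask)
        pair.scores["interface_identity"] = percent_identity(a, b) if mask else None
    else:
        pair.scores["interface_identity"] = None

    contact_pep = sorted({j for _, j in pair.contacts})
    best_sim, best_pep, best_aln = None, "", None
    for pep in phage_peptides:
        aln = align_peptides(pair.peptide_seq, pep, ptm_positions=pair.ptm_positions)
        if aln is None:
            continue
        if profile is not None:
            labels = peptide_position_classes(profile, pep)
            mask = {
                s
                for s in range(*aln.span)
                if labels[s - aln.offset] is not None
            }
        elif contact_pep:
            mask = {s for s in range(*aln.span) if s in contact_pep}
        else:
            mask = set(range(*aln.span))
        a = pair.peptide_seq
        b_full = ["-"] * len(a)
        for s in range(*aln.span):
            b_full[s] = pep[s - aln.offset]
        sim = percent_similarity(
            a, "".join(b_full), mask=mask, ptm_positions=pair.ptm_positions
        )
        if sim is None:
            continue
        if best_sim is None or sim > best_sim:
            best_sim, best_pep, best_aln = sim, pep, aln
    pair.scores["peptide_similarity"] = best_sim
    pair.matched_phage_peptide = best_pep
    pair.scores["peptide_alignment"] = best_aln
    return pair


def align_registers_identity(query: str, target: str) -> tuple[int, float] | None:
    """Best ungapped register of query on target by percent identity.

    Returns (offset, identity%) where target index t maps to query index
    t - offset; identity is over the overlap.
    """
    best = None
    min_overlap = min(3, len(query), len(target))
    for offset in range(-(len(query) - min_overlap), len(target) - min_overlap + 1):
        t_start = max(0, offset)
        t_stop = min(len(target), len(query) + offset)
        if t_stop - t_start < min_overlap:
            continue
        a = target[t_start:t_stop]
        b = query[t_start - offset : t_stop - offset]
        ident = percent_identity(a, b)
        if ident is None:
            continue
        key = (-ident, abs(offset), offset)
        if best is None or key < best[0]:
            best = (key, (offset, ident))
    return best[1] if best else None


def similarity_breakdown(
    pair: StructurePair,
    profile: SpecificityProfile | None = None,
) -> dict[str, float | None]:
    """Similarity of the matched phage peptide under four position masks.

    Masks are structure-peptide positions: in contact with the PRM vs not,
    and (when a profile is supplied) at specific vs non-specific logo
    positions. The matched peptide and its alignment must already be on the
    pair (see :func:`score_candidate`).
    """
    aln: PeptideAlignment | None = pair.scores.get("peptide_alignment")
    if aln is None or not pair.matched_phage_peptide:
        raise ValueError("pair has no matched phage peptide; run score_candidate first")
    pep = pair.matched_phage_peptide
    span = set(range(*aln.span))
    b_full = ["-"] * len(pair.peptide_seq)
    for s in span:
        b_full[s] = pep[s - aln.offset]
    b = "".join(b_full)

    contact_pep = {j for _, j in pair.contacts}
    masks: dict[str, set[int]] = {
        "contact": span & contact_pep,
        "non_contact": span - contact_pep,
    }
    if profile is not None:
        labels = peptide_position_classes(profile, pep)
        masks["specific"] = {
            s for s in span if labels[s - aln.offset] == "specific"
        }
        masks["non_specific"] = {
            s for s in span if labels[s - aln.offset] == "non-specific"
        }
    return {
        name: percent_similarity(
            pair.peptide_seq, b, mask=mask, ptm_positions=pair.ptm_positions
        )
        for name, mask in masks.items()
    }
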