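"""Molecular representation, MMP fragmentation and analog-series assembly.

A matched molecular pair (MMP) is a pair of compounds distinguished by a
chemical modification at a single site.  Single-cut fragmentation of eligible
exocyclic single bonds produces (core, substituent) splits; two compounds
sharing a single-cut core with different substituents form an MMP.  Series
assembly groups MMP-connected compounds, derives their maximum common core and
decomposes every member into one substituent per indexed substitution site.
"""

from __future__ import annotations

import csv
import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFMCS, rdRGroupDecomposition

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

DEFAULT_MAX_SUBSTITUENT_HEAVY_ATOMS = 13

_SITE_RE = re.compile(r"^R(\d+)$")


# ---------------------------------------------------------------------------
# small molecule helpers
# ---------------------------------------------------------------------------

def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonical_key(smiles_or_mol) -> str:
    """Canonical SMILES used as the identity key of a compound."""
    if isinstance(smiles_or_mol, Chem.Mol):
        return Chem.MolToSmiles(smiles_or_mol)
    return Chem.MolToSmiles(mol_from_smiles(smiles_or_mol))


def heavy_atom_count(fragment_smiles: str) -> int:
    """Number of heavy atoms in a fragment; dummy/attachment atoms excluded."""
    mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    if mol is None:
        raise ValueError(f"unparsable fragment: {fragment_smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def fragment_mol(fragment_smiles: str) -> Chem.Mol:
    """Parse a substituent fragment, tolerating explicit-H fragments."""
    mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    if mol is None:
        raise ValueError(f"unparsable fragment: {fragment_smiles!r}")
    Chem.SanitizeMol(
        mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS
    )
    return mol


def relabel_fragment(fragment_smiles: str, site_index: int) -> str:
    """Return the fragment with its attachment point mapped to ``site_index``."""
    mol = fragment_mol(fragment_smiles)
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise ValueError(
            f"fragment must have exactly one attachment point: {fragment_smiles!r}"
        )
    dummies[0].SetAtomMapNum(site_index)
    return Chem.MolToSmiles(mol)


def strip_attachment_label(fragment_smiles: str) -> str:
    """Canonical fragment with an unnumbered attachment point, for comparison."""
    mol = fragment_mol(fragment_smiles)
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def is_hydrogen_fragment(fragment_smiles: str) -> bool:
    return heavy_atom_count(fragment_smiles) == 0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

PROVENANCE_EXISTING = "existing"
PROVENANCE_VIRTUAL_DIAGNOSTIC = "virtual_diagnostic"
PROVENANCE_VIRTUAL_FW = "virtual_fw"


@dataclass
class Analog:
    """A compound: existing (with measured potency) or virtual."""

    id: str
    smiles: str
    potency: Optional[float] = None
    provenance: str = PROVENANCE_EXISTING
    _key: Optional[str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.potency is not None:
            p = float(self.potency)
            if p != p or p in (float("inf"), float("-inf")):
                raise ValueError(f"analog {self.id}: potency must be finite")
            self.potency = p

    @property
    def key(self) -> str:
        if self._key is None:
            self._key = canonical_key(self.smiles)
        return self._key


@dataclass
class CoreScaffold:
    """Core with indexed open attachment points ``[*:i]`` for sites R1..Rk."""

    smiles: str
    site_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mol = mol_from_smiles(self.smiles)
        indices = sorted(
            a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0
        )
        if not indices:
            raise ValueError("core has no attachment points")
        if len(set(indices)) != len(indices):
            raise ValueError("core attachment-point labels must be unique")
        if not self.site_labels:
            self.site_labels = tuple(f"R{i}" for i in indices)
        self.smiles = Chem.MolToSmiles(mol)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def site_indices(self) -> tuple[int, ...]:
        return tuple(int(_SITE_RE.match(s).group(1)) for s in self.site_labels)

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass
class MMPEdge:
    """Two analogs differing by a substituent exchange at a single site.

    ``site`` is the series substitution-site label once the pair has been
    placed in a series; for raw fragmentation output it may be ``None`` and
    ``cut_core`` records the shared single-cut core instead.
    """

    analog_a: str
    analog_b: str
    site: Optional[str]
    substituent_a: str
    substituent_b: str
    cut_core: Optional[str] = None

    def __post_init__(self) -> None:
        if self.analog_a == self.analog_b:
            raise ValueError("self-MMP is not allowed")
        if self.analog_a > self.analog_b:
            self.analog_a, self.analog_b = self.analog_b, self.analog_a
            self.substituent_a, self.substituent_b = (
                self.substituent_b,
                self.substituent_a,
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.analog_a, self.analog_b)

    def other(self, analog_id: str) -> str:
        if analog_id == self.analog_a:
            return self.analog_b
        if analog_id == self.analog_b:
            return self.analog_a
        raise KeyError(analog_id)

    def substituent_of(self, analog_id: str) -> str:
        if analog_id == self.analog_a:
            return self.substituent_a
        if analog_id == self.analog_b:
            return self.substituent_b
        raise KeyError(analog_id)


@dataclass
class MMPNetwork:
    """Undirected MMP graph over analog ids."""

    nodes: list[str]
    edges: list[MMPEdge]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.pair in seen:
                raise ValueError(f"duplicate MMP edge {e.pair}")
            seen.add(e.pair)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.analog_a, e.analog_b, edge=e)
        return g

    def incident(self, analog_id: str) -> list[MMPEdge]:
        return [e for e in self.edges if analog_id in e.pair]


@dataclass
class AnalogSeries:
    """Analogs sharing one core, each decomposed into per-site substituents."""

    series_id: str
    core: CoreScaffold
    members: list[Analog]
    substituents: dict[str, dict[str, str]]  # analog id -> {site -> fragment}
    target_label: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [a.id for a in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate analog ids in series")
        missing = set(ids) - set(self.substituents)
        if missing:
            raise ValueError(f"members without substituent assignment: {missing}")
        sites = set(self.core.site_labels)
        for aid, table in self.substituents.items():
            if set(table) != sites:
                raise ValueError(
                    f"analog {aid}: substituent table sites {set(table)} != {sites}"
                )

    @property
    def member_ids(self) -> list[str]:
        return [a.id for a in self.members]

    @property
    def member_keys(self) -> set[str]:
        return {a.key for a in self.members}

    def member(self, analog_id: str) -> Analog:
        for a in self.members:
            if a.id == analog_id:
                return a
        raise KeyError(analog_id)

    def potency_map(self) -> dict[str, float]:
        return {a.id: a.potency for a in self.members if a.potency is not None}

    def site_substituents(self, site: str) -> list[str]:
        """Unique substituent fragments observed at ``site`` among members."""
        seen: dict[str, None] = {}
        for table in self.substituents.values():
            seen.setdefault(table[site], None)
        return list(seen)

    def hydrogen_frequency(self, site: str) -> float:
        """Fraction of members carrying hydrogen at ``site``."""
        n = len(self.members)
        if n == 0:
            return 0.0
        h = sum(
            1
            for table in self.substituents.values()
            if is_hydrogen_fragment(table[site])
        )
        return h / n


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

def _eligible_bond(bond: Chem.Bond) -> bool:
    """Cut rule: acyclic single bond with a ring atom or an N/O terminus.

    The N/O condition captures the standard retrosynthetic motifs (amide,
    ester, ether, amine attachments) without an explicit SMARTS battery.
    """
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
        return False
    if a.IsInRing() or b.IsInRing():
        return True
    return a.GetAtomicNum() in (7, 8) or b.GetAtomicNum() in (7, 8)


def single_cut_fragments(
    mol: Chem.Mol, max_substituent_heavy_atoms: int = DEFAULT_MAX_SUBSTITUENT_HEAVY_ATOMS
) -> list[tuple[str, str]]:
    """All (core, substituent) splits from one eligible single-bond cut.

    Both fragments carry a bare ``[*]`` attachment point.  Each eligible bond
    yields up to two orientations; the substituent side must respect the
    heavy-atom cap and may not exceed the core side in size.
    """
    out: list[tuple[str, str]] = []
    for bond in mol.GetBonds():
        if not _eligible_bond(bond):
            continue
        frag = Chem.FragmentOnBonds(mol, [bond.GetIdx()], dummyLabels=[(0, 0)])
        try:
            pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
        except Chem.AtomValenceException:  # pragma: no cover - defensive
            continue
        if len(pieces) != 2:
            continue
        smi = [Chem.MolToSmiles(p) for p in pieces]
        ha = [heavy_atom_count(s) for s in smi]
        for sub_idx in (0, 1):
            core_idx = 1 - sub_idx
            if ha[sub_idx] <= max_substituent_heavy_atoms and ha[sub_idx] <= ha[core_idx]:
                out.append((smi[core_idx], smi[sub_idx]))
    return out


def _hydrogen_capped(core_smiles: str) -> Optional[str]:
    """Canonical key of a single-cut core with its attachment point H-capped."""
    mol = Chem.MolFromSmiles(core_smiles, sanitize=False)
    if mol is None:
        return None
    rw = Chem.RWMol(mol)
    dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        return None
    rw.RemoveAtom(dummies[0])
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def fragment_mmp(
    compound_set: Sequence[Analog],
    max_substituent_heavy_atoms: int = DEFAULT_MAX_SUBSTITUENT_HEAVY_ATOMS,
    errors: Optional[list[dict]] = None,
) -> list[MMPEdge]:
    """All MMP relationships under single-cut fragmentation.

    Parameters
    ----------
    compound_set:
        Analogs to pair up.  Unparsable structures are recorded in ``errors``
        (if given) and skipped.
    max_substituent_heavy_atoms:
        Cap on the exchanged-fragment size (default 13 heavy atoms).
    errors:
        Optional sink for per-compound error records
        ``{"id": ..., "error": ...}``.

    Returns
    -------
    One :class:`MMPEdge` per unordered compound pair sharing at least one
    single-cut core; when several shared cores exist the largest one (by heavy
    atoms, ties broken lexicographically) defines the exchange.
    """
    cuts_by_core: dict[str, dict[str, str]] = {}
    key_to_ids: dict[str, list[str]] = {}
    for analog in compound_set:
        try:
            mol = mol_from_smiles(analog.smiles)
        except ValueError as exc:
            logger.warning("skipping %s: %s", analog.id, exc)
            if errors is not None:
                errors.append({"id": analog.id, "error": str(exc)})
            continue
        key_to_ids.setdefault(analog.key, []).append(analog.id)
        for core_smi, sub_smi in single_cut_fragments(
            mol, max_substituent_heavy_atoms
        ):
            cuts_by_core.setdefault(core_smi, {})[analog.id] = sub_smi

    # hydrogen as a substituent: a compound identical to a cut core with the
    # attachment point hydrogen-capped carries [H] at that core
    for core_smi, by_analog in cuts_by_core.items():
        capped = _hydrogen_capped(core_smi)
        if capped is None:
            continue
        for cid in key_to_ids.get(capped, []):
            by_analog.setdefault(cid, "[H][*]")

    best: dict[tuple[str, str], tuple[int, str, MMPEdge]] = {}
    for core_smi, by_analog in cuts_by_core.items():
        if len(by_analog) < 2:
            continue
        core_ha = heavy_atom_count(core_smi)
        for (id_a, sub_a), (id_b, sub_b) in itertools.combinations(
            sorted(by_analog.items()), 2
        ):
            if strip_attachment_label(sub_a) == strip_attachment_label(sub_b):
                continue  # identical substituent: same compound region, no MMP
            edge = MMPEdge(
                analog_a=id_a,
                analog_b=id_b,
                site=None,
                substituent_a=sub_a,
                substituent_b=sub_b,
                cut_core=core_smi,
            )
            cur = best.get(edge.pair)
            cand = (core_ha, core_smi, edge)
            if cur is None or (cand[0], cand[1]) > (cur[0], cur[1]):
                best[edge.pair] = cand
    return [t[2] for _, t in sorted(best.items())]


# ---------------------------------------------------------------------------
# series assembly
# ---------------------------------------------------------------------------

def _derive_core(mols: Sequence[Chem.Mol]) -> Optional[Chem.Mol]:
    """Maximum common core of a set of molecules (ring-complete MCS)."""
    if len(mols) == 1:
        return Chem.Mol(mols[0])
    res = rdFMCS.FindMCS(
        list(mols),
        ringMatchesRingOnly=True,
        completeRingsOnly=True,
        timeout=30,
    )
    if res.canceled or res.numAtoms < 3:
        return None
    return Chem.MolFromSmarts(res.smartsString)


def _decompose_component(
    analogs: Sequence[Analog],
) -> Optional[tuple[CoreScaffold, dict[str, dict[str, str]], list[str]]]:
    """Derive a labelled core and per-member substituent tables via RGD."""
    mols = []
    for a in analogs:
        mols.append(mol_from_smiles(a.smiles))
    core_query = _derive_core(mols)
    if core_query is None:
        return None
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.onlyMatchAtRGroups = False
    params.removeHydrogensPostMatch = True
    try:
        rows, unmatched = rdRGroupDecomposition.RGroupDecompose(
            [core_query], mols, asSmiles=True, options=params
        )
    except Exception as exc:  # pragma: no cover - RDKit internal failures
        logger.warning("R-group decomposition failed: %s", exc)
        return None
    matched = [a for i, a in enumerate(analogs) if i not in set(unmatched)]
    if len(matched) < 2 or not rows:
        return None
    core_smiles = rows[0]["Core"]
    core_mol = Chem.MolFromSmiles(core_smiles)
    if core_mol is None:
        return None
    site_idx = sorted(
        a.GetAtomMapNum() for a in core_mol.GetAtoms() if a.GetAtomicNum() == 0
    )
    if not site_idx:
        return None
    core = CoreScaffold(smiles=core_smiles)
    tables: dict[str, dict[str, str]] = {}
    for analog, row in zip(matched, rows):
        table = {}
        for i in site_idx:
            frag = row.get(f"R{i}", f"[H][*:{i}]")
            table[f"R{i}"] = Chem.MolToSmiles(fragment_mol(frag))
        tables[analog.id] = table
    leftovers = [a.id for i, a in enumerate(analogs) if i in set(unmatched)]
    return core, tables, leftovers


def assemble_series(
    compound_set: Sequence[Analog],
    mmp_edges: Sequence[MMPEdge],
    min_size: int = 2,
    series_prefix: str = "AS",
) -> list[AnalogSeries]:
    """Partition MMP-connected compounds into analog series.

    Connected components of the MMP graph are candidate series; for each, the
    maximum common core is derived and every member is decomposed into one
    substituent per indexed site.  Compounds in no component (or failing core
    matching) are leftovers and excluded from the output.
    """
    by_id = {a.id: a for a in compound_set}
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for e in mmp_edges:
        g.add_edge(e.analog_a, e.analog_b)

    series: list[AnalogSeries] = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c))
    counter = 0
    for comp in components:
        ids = sorted(comp)
        if len(ids) < min_size:
            continue
        analogs = [by_id[i] for i in ids]
        result = _decompose_component(analogs)
        if result is None:
            logger.warning("component %s: no common core found, skipped", ids[:3])
            continue
        core, tables, leftovers = result
        if leftovers:
            logger.warning("component: %d members did not match core", len(leftovers))
        kept = [a for a in analogs if a.id in tables]
        if len(kept) < min_size:
            continue
        if core.n_sites > 6:
            logger.warning(
                "series with %d substitution sites exceeds the expected 1-6 range",
                core.n_sites,
            )
        counter += 1
        series.append(
            AnalogSeries(
                series_id=f"{series_prefix}{counter}",
                core=core,
                members=kept,
                substituents=tables,
            )
        )
    return series


# ---------------------------------------------------------------------------
# decomposition / recomposition
# ---------------------------------------------------------------------------

def decompose(analog: Analog, core: CoreScaffold) -> dict[str, str]:
    """Per-site substituent table of ``analog`` against ``core``.

    Raises ``ValueError`` when the analog does not contain the core.
    """
    mol = mol_from_smiles(analog.smiles)
    params = rdRGroupDecomposition.RGroupDecompositionParameters()
    params.onlyMatchAtRGroups = True
    params.removeHydrogensPostMatch = True
    rows, unmatched = rdRGroupDecomposition.RGroupDecompose(
        [core.mol()], [mol], asSmiles=True, options=params
    )
    if unmatched or not rows:
        raise ValueError(f"analog {analog.id} does not match the series core")
    row = rows[0]
    table = {}
    for label, idx in zip(core.site_labels, core.site_indices):
        frag = row.get(f"R{idx}", f"[H][*:{idx}]")
        table[label] = Chem.MolToSmiles(fragment_mol(frag))
    return table


def recompose(core: CoreScaffold, substituents: Mapping[str, str]) -> str:
    """Canonical SMILES of core + one substituent per site (H allowed).

    A substituent fragment may carry several attachment points (all bonded to
    the same site's core atom, as produced by R-group decomposition of e.g.
    carbonyl-bearing positions); bond orders at the attachment points are
    preserved.  Raises ``ValueError`` on chemically invalid recombination.
    """
    rw = Chem.RWMol(core.mol())
    anchors: dict[int, int] = {}
    core_dummies: list[int] = []
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            nbrs = atom.GetNeighbors()
            if len(nbrs) != 1:
                raise ValueError("core attachment point must have one neighbor")
            anchors[atom.GetAtomMapNum()] = nbrs[0].GetIdx()
            core_dummies.append(atom.GetIdx())

    for label, idx in zip(core.site_labels, core.site_indices):
        frag_smi = substituents.get(label)
        if frag_smi is None:
            raise ValueError(f"missing substituent for site {label}")
        frag = fragment_mol(frag_smi)
        if is_hydrogen_fragment(frag_smi):
            continue  # removing the dummy leaves an implicit hydrogen
        offset = rw.GetNumAtoms()
        frag_dummies: list[tuple[int, int, Chem.BondType]] = []
        index_map: dict[int, int] = {}
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                continue
            a = Chem.Atom(atom)
            a.SetAtomMapNum(0)
            index_map[atom.GetIdx()] = rw.AddAtom(a)
        n_attach = 0
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() != 0:
                continue
            n_attach += 1
            for nbr in atom.GetNeighbors():
                bond = frag.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
                frag_dummies.append(
                    (atom.GetIdx(), nbr.GetIdx(), bond.GetBondType())
                )
        if n_attach < 1:
            raise ValueError(f"substituent for {label} has no attachment point")
        for bond in frag.GetBonds():
            if bond.GetBeginAtom().GetAtomicNum() == 0:
                continue
            if bond.GetEndAtom().GetAtomicNum() == 0:
                continue
            rw.AddBond(
                index_map[bond.GetBeginAtomIdx()],
                index_map[bond.GetEndAtomIdx()],
                bond.GetBondType(),
            )
        del offset
        for _, nbr_idx, btype in frag_dummies:
            rw.AddBond(anchors[idx], index_map[nbr_idx], btype)

    for dummy_idx in sorted(core_dummies, reverse=True):
        rw.RemoveAtom(dummy_idx)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        out = Chem.RemoveHs(out)
    except Exception as exc:
        raise ValueError(f"invalid recombination: {exc}") from exc
    return Chem.MolToSmiles(out)


def build_network(
    series: AnalogSeries,
    max_substituent_heavy_atoms: int = DEFAULT_MAX_SUBSTITUENT_HEAVY_ATOMS,
) -> MMPNetwork:
    """MMP network over series members from their substituent tables.

    Two members are an MMP iff their tables differ at exactly one site and
    both exchanged fragments respect the heavy-atom cap.  Site labels of the
    resulting edges refer to the series core.
    """
    ids = series.member_ids
    edges: list[MMPEdge] = []
    for id_a, id_b in itertools.combinations(sorted(ids), 2):
        ta, tb = series.substituents[id_a], series.substituents[id_b]
        diff = [s for s in series.core.site_labels if ta[s] != tb[s]]
        if len(diff) != 1:
            continue
        site = diff[0]
        if (
            heavy_atom_count(ta[site]) > max_substituent_heavy_atoms
            or heavy_atom_count(tb[site]) > max_substituent_heavy_atoms
        ):
            continue
        edges.append(
            MMPEdge(
                analog_a=id_a,
                analog_b=id_b,
                site=site,
                substituent_a=ta[site],
                substituent_b=tb[site],
            )
        )
    return MMPNetwork(nodes=list(ids), edges=edges)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_smi(path: str) -> list[Analog]:
    """Read a .smi file: one ``SMILES id`` pair per line, whitespace separated."""
    out: list[Analog] = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{n}"
            out.append(Analog(id=cid, smiles=smiles))
    return out


def read_compound_csv(path: str) -> list[Analog]:
    """Read a compound table CSV with columns id, smiles[, potency]."""
    out: list[Analog] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            pot = row.get("potency")
            out.append(
                Analog(
                    id=row["id"],
                    smiles=row["smiles"],
                    potency=float(pot) if pot not in (None, "", "NA") else None,
                )
            )
    return out


def read_sdf(path: str, potency_tag: str = "potency") -> list[Analog]:
    """Read an SD file; potency taken from the named property tag."""
    out: list[Analog] = []
    for i, mol in enumerate(Chem.SDMolSupplier(path)):
        if mol is None:
            logger.warning("unparsable SDF record %d", i)
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"
        pot = float(mol.GetProp(potency_tag)) if mol.HasProp(potency_tag) else None
        out.append(Analog(id=cid or f"sdf{i}", smiles=Chem.MolToSmiles(mol), potency=pot))
    return out


def write_series_csv(series_list: Sequence[AnalogSeries], path: str) -> None:
    """Series member table: series id, compound id, per-site assignment, potency."""
    max_sites = max((s.core.n_sites for s in series_list), default=0)
    site_cols = [f"R{i+1}" for i in range(max_sites)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["series_id", "compound_id", "smiles", "potency", *site_cols])
        for s in series_list:
            for a in s.members:
                table = s.substituents[a.id]
                row = [s.series_id, a.id, a.smiles, a.potency]
                row += [table.get(c, "") for c in site_cols]
                w.writerow(row)


def write_edges_csv(edges: Iterable[MMPEdge], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["analog_a", "analog_b", "site", "substituent_a", "substituent_b"]
        )
        for e in edges:
            w.writerow([e.analog_a, e.analog_b, e.site, e.substituent_a, e.substituent_b])
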