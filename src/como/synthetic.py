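"""Synthetic analog series and substituent pools with controlled structure.

Series are built on a real (quinoline) scaffold with up to six
symmetry-inequivalent substitution sites, so that fingerprint and descriptor
stages are exercised with genuine chemistry.  Potencies follow an additive
per-site model plus optional pairwise interaction terms and Gaussian noise;
with both switched off the landscape is exactly additive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from como.chem import (
    Analog,
    AnalogSeries,
    CoreScaffold,
    heavy_atom_count,
    recompose,
    relabel_fragment,
    strip_attachment_label,
)

logger = logging.getLogger(__name__)

_SCAFFOLD_SMILES = "c1ccc2ncccc2c1"  # quinoline: 7 inequivalent CH positions

HYDROGEN_FRAGMENT = "[H][*]"

# grammar pieces for the fragment generator: divalent linkers and monovalent
# terminal groups, all concatenation-safe in SMILES
_LINKERS = ["C", "CC", "O", "N", "C(=O)", "C(C)"]
_TERMINALS = [
    "C",
    "CC",
    "F",
    "Cl",
    "Br",
    "O",
    "N",
    "C#N",
    "C(F)(F)F",
    "c1ccccc1",
    "c1ccncc1",
    "C1CC1",
    "C(C)C",
    "C(=O)N",
    "C(=O)O",
]


def _core_template(n_sites: int) -> CoreScaffold:
    """Quinoline core with ``n_sites`` labelled attachment points."""
    if not 1 <= n_sites <= 6:
        raise ValueError("n_sites must be between 1 and 6")
    base = Chem.MolFromSmiles(_SCAFFOLD_SMILES)
    ranks = list(Chem.CanonicalRankAtoms(base))
    ch = [
        a.GetIdx()
        for a in base.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 1
    ]
    ch.sort(key=lambda i: ranks[i])
    rw = Chem.RWMol(base)
    for site, idx in enumerate(ch[:n_sites], start=1):
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(site)
        j = rw.AddAtom(dummy)
        rw.AddBond(idx, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return CoreScaffold(smiles=Chem.MolToSmiles(mol))


def _random_fragment(rng: np.random.Generator, max_heavy_atoms: int) -> str:
    n_link = int(rng.integers(0, 4))
    parts = [str(rng.choice(_LINKERS)) for _ in range(n_link)]
    parts.append(str(rng.choice(_TERMINALS)))
    smi = "[*]" + "".join(parts)
    frag = Chem.MolFromSmiles(smi)
    if frag is None:  # pragma: no cover - grammar is concatenation-safe
        return ""
    canonical = strip_attachment_label(Chem.MolToSmiles(frag))
    if heavy_atom_count(canonical) > max_heavy_atoms:
        return ""
    return canonical


def make_pool(
    n_fragments: int,
    max_heavy_atoms: int = 13,
    seed: int = 0,
    source_tag: str = "synthetic",
):
    """Generate a pool of unique single-attachment substituent fragments.

    Fragments are drawn from a linker/terminal grammar until ``n_fragments``
    unique ones are collected (or the grammar is exhausted, with a warning).
    """
    from como.diagnostics import SubstituentPool

    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    attempts = stall = 0
    max_attempts = max(500 * n_fragments, 10_000)
    while len(seen) < n_fragments and attempts < max_attempts and stall < 2000:
        attempts += 1
        frag = _random_fragment(rng, max_heavy_atoms)
        before = len(seen)
        if frag:
            seen.setdefault(frag, None)
        stall = 0 if len(seen) > before else stall + 1
    if len(seen) < n_fragments:
        logger.warning(
            "fragment grammar exhausted: %d/%d unique fragments generated",
            len(seen),
            n_fragments,
        )
    return SubstituentPool(fragments=list(seen), source_tag=source_tag)


@dataclass
class LandscapeSpec:
    """Recipe for a synthetic analog series with additive potency structure.

    ``site_contributions[s][j]`` is the additive potency term of substituent
    ``j`` at site ``s`` (0-based).  ``nonadditivity`` maps pairs of
    (site, substituent-index) coordinates to pairwise interaction terms.
    ``occupancy`` is the fraction of the full substituent lattice that is
    instantiated as existing analogs.
    """

    n_sites: int = 2
    substituents_per_site: tuple[int, ...] | int = 3
    base_potency: float = 6.0
    site_contributions: Optional[list[list[float]]] = None
    nonadditivity: dict[tuple[tuple[int, int], tuple[int, int]], float] = field(
        default_factory=dict
    )
    noise_sd: float = 0.0
    occupancy: float = 1.0
    seed: int = 0
    contribution_sd: float = 0.5
    hydrogen_sites: tuple[int, ...] = ()  # 1-based sites where H is a substituent
    max_heavy_atoms: int = 13

    def __post_init__(self) -> None:
        if not 1 <= self.n_sites <= 6:
            raise ValueError("n_sites must be between 1 and 6")
        if isinstance(self.substituents_per_site, int):
            self.substituents_per_site = (self.substituents_per_site,) * self.n_sites
        self.substituents_per_site = tuple(self.substituents_per_site)
        if len(self.substituents_per_site) != self.n_sites:
            raise ValueError("substituents_per_site length must equal n_sites")
        if any(c < 1 for c in self.substituents_per_site):
            raise ValueError("each site needs at least one substituent")
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.site_contributions is not None:
            if len(self.site_contributions) != self.n_sites or any(
                len(c) != n
                for c, n in zip(self.site_contributions, self.substituents_per_site)
            ):
                raise ValueError("site_contributions shape mismatch")
        for (a, b) in self.nonadditivity:
            for site, sub in (a, b):
                if not 0 <= site < self.n_sites:
                    raise ValueError(f"interaction references invalid site {site}")
                if not 0 <= sub < self.substituents_per_site[site]:
                    raise ValueError(
                        f"interaction references invalid substituent {sub} at site {site}"
                    )

    @property
    def lattice_size(self) -> int:
        return int(np.prod(self.substituents_per_site))


@dataclass
class GroundTruth:
    """Full-lattice truth accompanying a generated series."""

    spec: LandscapeSpec
    core: CoreScaffold
    site_substituents: list[list[str]]  # per site, fragment per substituent idx
    lattice: dict[tuple[int, ...], float]  # cell -> noise-free potency
    keys: dict[tuple[int, ...], str]  # cell -> canonical compound key
    observed_cells: list[tuple[int, ...]]

    def cell_table(self, cell: tuple[int, ...]) -> dict[str, str]:
        return {
            f"R{s + 1}": relabel_fragment(self.site_substituents[s][j], s + 1)
            for s, j in enumerate(cell)
        }


def _truth_value(spec: LandscapeSpec, contributions, cell) -> float:
    value = spec.base_potency + sum(
        contributions[s][j] for s, j in enumerate(cell)
    )
    for ((s1, j1), (s2, j2)), delta in spec.nonadditivity.items():
        if cell[s1] == j1 and cell[s2] == j2:
            value += delta
    return value


def make_series(
    spec: LandscapeSpec, series_id: str = "SYN1"
) -> tuple[AnalogSeries, GroundTruth]:
    """Build a chemically valid analog series realizing ``spec``.

    Returns the series (occupied lattice cells, noisy potencies) together
    with the noise-free truth for every cell of the full lattice.
    """
    rng = np.random.default_rng(spec.seed)
    core = _core_template(spec.n_sites)

    pool = make_pool(
        n_fragments=sum(spec.substituents_per_site) + 8,
        max_heavy_atoms=spec.max_heavy_atoms,
        seed=spec.seed + 7919,
    )
    fragments = list(pool.fragments)
    rng.shuffle(fragments)
    site_substituents: list[list[str]] = []
    cursor = 0
    for s, count in enumerate(spec.substituents_per_site):
        subs: list[str] = []
        if (s + 1) in spec.hydrogen_sites:
            subs.append(HYDROGEN_FRAGMENT)
        while len(subs) < count:
            if cursor >= len(fragments):
                raise ValueError("fragment pool exhausted while assigning sites")
            subs.append(fragments[cursor])
            cursor += 1
        site_substituents.append(subs[:count])

    if spec.site_contributions is not None:
        contributions = [list(c) for c in spec.site_contributions]
    else:
        contributions = [
            list(rng.normal(0.0, spec.contribution_sd, size=count))
            for count in spec.substituents_per_site
        ]

    cells = list(itertools.product(*[range(c) for c in spec.substituents_per_site]))
    lattice: dict[tuple[int, ...], float] = {}
    keys: dict[tuple[int, ...], str] = {}
    tables: dict[tuple[int, ...], dict[str, str]] = {}
    for cell in cells:
        table = {
            f"R{s + 1}": relabel_fragment(site_substituents[s][j], s + 1)
            for s, j in enumerate(cell)
        }
        tables[cell] = table
        keys[cell] = recompose(core, table)
        lattice[cell] = _truth_value(spec, contributions, cell)

    if len(set(keys.values())) != len(cells):
        raise ValueError("lattice cells collide to identical structures")

    n_obs = max(2, int(round(spec.occupancy * len(cells))))
    n_obs = min(n_obs, len(cells))
    chosen = sorted(
        tuple(cells[i]) for i in rng.choice(len(cells), size=n_obs, replace=False)
    )

    members: list[Analog] = []
    substituents: dict[str, dict[str, str]] = {}
    for n, cell in enumerate(chosen, start=1):
        noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        aid = f"{series_id}-{n:04d}"
        members.append(
            Analog(id=aid, smiles=keys[cell], potency=lattice[cell] + noise)
        )
        substituents[aid] = tables[cell]

    series = AnalogSeries(
        series_id=series_id, core=core, members=members, substituents=substituents
    )
    truth = GroundTruth(
        spec=spec,
        core=core,
        site_substituents=site_substituents,
        lattice=lattice,
        keys=keys,
        observed_cells=chosen,
    )
    return series, truth


def spec_to_dict(spec: LandscapeSpec) -> dict:
    """Serializable form of a landscape spec (for YAML round-trips)."""
    return {
        "n_sites": spec.n_sites,
        "substituents_per_site": list(spec.substituents_per_site),
        "base_potency": spec.base_potency,
        "site_contributions": spec.site_contributions,
        "nonadditivity": [
            {"a": list(a), "b": list(b), "delta": d}
            for (a, b), d in spec.nonadditivity.items()
        ],
        "noise_sd": spec.noise_sd,
        "occupancy": spec.occupancy,
        "seed": spec.seed,
        "contribution_sd": spec.contribution_sd,
        "hydrogen_sites": list(spec.hydrogen_sites),
        "max_heavy_atoms": spec.max_heavy_atoms,
    }


def spec_from_dict(data: dict) -> LandscapeSpec:
    nonadd = {
        (tuple(item["a"]), tuple(item["b"])): item["delta"]
        for item in data.get("nonadditivity", []) or []
    }
    return LandscapeSpec(
        n_sites=data.get("n_sites", 2),
        substituents_per_site=tuple(data.get("substituents_per_site", (3, 3))),
        base_potency=data.get("base_potency", 6.0),
        site_contributions=data.get("site_contributions"),
        nonadditivity=nonadd,
        noise_sd=data.get("noise_sd", 0.0),
        occupancy=data.get("occupancy", 1.0),
        seed=data.get("seed", 0),
        contribution_sd=data.get("contribution_sd", 0.5),
        hydrogen_sites=tuple(data.get("hydrogen_sites", ())),
        max_heavy_atoms=data.get("max_heavy_atoms", 13),
    )
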