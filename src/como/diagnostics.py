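"""Virtual-analog enumeration, reference space and saturation/progression scores.

Chemical saturation of an analog series is assessed by enumerating a virtual
analog (VA) population on the series core, projecting existing analogs (EAs)
and VAs into a normalized descriptor space, and analyzing which VAs fall into
EA neighborhoods (NBHs, Euclidean balls of a fixed radius):

* coverage       ``C = n_N / n_V``
* sampling depth ``d_mean = NBH_O_VA / n_N`` (mean NBH membership of in-NBH VAs)
* density        ``D = 1 - 1 / d_mean``
* saturation     ``S = 2CD / (C + D)`` (harmonic mean)

SAR progression ``P`` is the weighted mean, over VAs shared by several NBHs,
of the mean absolute pairwise potency difference among the EAs sharing them.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from scipy.spatial.distance import cdist

from como.chem import (
    PROVENANCE_VIRTUAL_DIAGNOSTIC,
    Analog,
    AnalogSeries,
    heavy_atom_count,
    mol_from_smiles,
    recompose,
    relabel_fragment,
    strip_attachment_label,
)

logger = logging.getLogger(__name__)

DEFAULT_N_VA = 2000
DEFAULT_RADIUS = 1.0

#: the 7 default physicochemical descriptors spanning the reference space
DEFAULT_DESCRIPTORS = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "RingCount",
)

_DESCRIPTOR_FUNCS = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumHDonors": Lipinski.NumHDonors,
    "NumHAcceptors": Lipinski.NumHAcceptors,
    "NumRotatableBonds": Lipinski.NumRotatableBonds,
    "RingCount": rdMolDescriptors.CalcNumRings,
}


@dataclass
class SubstituentPool:
    """Unique single-attachment-point fragments for VA enumeration."""

    fragments: list[str]
    source_tag: str = "user"
    max_heavy_atoms: int = 13

    def __post_init__(self) -> None:
        canon: dict[str, None] = {}
        for frag in self.fragments:
            smi = strip_attachment_label(frag)
            mol = Chem.MolFromSmiles(smi, sanitize=False)
            n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
            if n_attach != 1:
                raise ValueError(
                    f"fragment {frag!r} must have exactly one attachment point"
                )
            if heavy_atom_count(smi) > self.max_heavy_atoms:
                raise ValueError(
                    f"fragment {frag!r} exceeds {self.max_heavy_atoms} heavy atoms"
                )
            canon.setdefault(smi, None)
        self.fragments = list(canon)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class ReferenceSpace:
    """Z-normalized descriptor coordinates of EAs and VAs."""

    descriptor_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    ea_ids: list[str]
    va_ids: list[str]
    ea_coords: np.ndarray  # (n_ea, dim)
    va_coords: np.ndarray  # (n_va, dim)

    @property
    def dimension(self) -> int:
        return len(self.descriptor_names)


@dataclass
class NeighborhoodModel:
    """VA membership in EA neighborhoods of a fixed radius."""

    radius: float
    ea_ids: list[str]
    va_ids: list[str]
    membership: np.ndarray  # (n_va, n_ea) boolean

    @property
    def n_v(self) -> int:
        return len(self.va_ids)

    @property
    def multiplicity(self) -> np.ndarray:
        """m_i: number of EA neighborhoods containing each VA."""
        return self.membership.sum(axis=1)

    @property
    def n_n(self) -> int:
        """Number of VAs falling into at least one NBH."""
        return int((self.multiplicity > 0).sum())

    def members_of(self, va_index: int) -> list[str]:
        return [e for e, m in zip(self.ea_ids, self.membership[va_index]) if m]


@dataclass
class ScoreReport:
    """Per-series diagnostic scores with provenance."""

    series_id: str
    C: float
    d_mean: Optional[float]
    D: float
    S: float
    P: Optional[float]
    N: Optional[float]
    counts: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "series_id": self.series_id,
            "C": self.C,
            "d_mean": self.d_mean,
            "D": self.D,
            "S": self.S,
            "P": self.P,
            "N": self.N,
            "counts": dict(self.counts),
            "parameters": dict(self.parameters),
        }

    def to_row(self) -> dict:
        row = {
            "series_id": self.series_id,
            "C": self.C,
            "d_mean": self.d_mean,
            "D": self.D,
            "S": self.S,
            "P": self.P,
            "N": self.N,
        }
        row.update({f"n_{k}" if not k.startswith("n") else k: v for k, v in self.counts.items()})
        return row


# ---------------------------------------------------------------------------
# VA enumeration
# ---------------------------------------------------------------------------

def enumerate_diagnostic_vas(
    series: AnalogSeries,
    pool: SubstituentPool,
    n_va: int = DEFAULT_N_VA,
    seed: int = 0,
) -> list[Analog]:
    """Enumerate up to ``n_va`` unique diagnostic VAs on the series core.

    At each site, hydrogen is drawn with probability equal to its observed
    frequency among the EAs at that site; otherwise a substituent is drawn
    uniformly from the pool.  VAs identical to an EA are rejected.  The
    result is deterministic for a given seed.
    """
    if n_va < 1:
        raise ValueError("n_va must be >= 1")
    if len(pool) == 0:
        raise ValueError("substituent pool is empty")
    rng = np.random.default_rng(seed)
    sites = series.core.site_labels
    indices = series.core.site_indices
    h_freq = {s: series.hydrogen_frequency(s) for s in sites}
    ea_keys = series.member_keys

    vas: list[Analog] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = max(50 * n_va, 2000)
    while len(vas) < n_va and attempts < max_attempts:
        attempts += 1
        table = {}
        for s, idx in zip(sites, indices):
            if rng.random() < h_freq[s]:
                frag = "[H][*]"
            else:
                frag = pool.fragments[int(rng.integers(len(pool)))]
            table[s] = relabel_fragment(frag, idx)
        try:
            key = recompose(series.core, table)
        except ValueError:
            continue
        if key in ea_keys or key in seen:
            continue
        seen.add(key)
        vas.append(
            Analog(
                id=f"{series.series_id}-VA{len(vas) + 1:05d}",
                smiles=key,
                provenance=PROVENANCE_VIRTUAL_DIAGNOSTIC,
            )
        )
    if len(vas) < n_va:
        logger.warning(
            "series %s: only %d/%d unique VAs could be enumerated",
            series.series_id,
            len(vas),
            n_va,
        )
    return vas


# ---------------------------------------------------------------------------
# reference space & neighborhoods
# ---------------------------------------------------------------------------

def compute_descriptors(
    analogs: Sequence[Analog], descriptor_names: Sequence[str]
) -> np.ndarray:
    funcs = []
    for name in descriptor_names:
        if name not in _DESCRIPTOR_FUNCS:
            raise KeyError(
                f"unknown descriptor {name!r}; available: {sorted(_DESCRIPTOR_FUNCS)}"
            )
        funcs.append(_DESCRIPTOR_FUNCS[name])
    rows = np.empty((len(analogs), len(funcs)))
    for i, analog in enumerate(analogs):
        mol = mol_from_smiles(analog.smiles)
        rows[i] = [f(mol) for f in funcs]
    return rows


def build_reference_space(
    eas: Sequence[Analog],
    vas: Sequence[Analog],
    descriptor_names: Sequence[str] = DEFAULT_DESCRIPTORS,
) -> ReferenceSpace:
    """Descriptor space z-normalized over the combined EA + VA population."""
    if len(eas) + len(vas) < 2:
        raise ValueError("need at least two compounds to fit the reference space")
    ea_mat = compute_descriptors(eas, descriptor_names)
    va_mat = compute_descriptors(vas, descriptor_names) if vas else np.empty(
        (0, len(descriptor_names))
    )
    both = np.vstack([ea_mat, va_mat])
    center = both.mean(axis=0)
    scale = both.std(axis=0)
    zero = scale < 1e-12
    if zero.any():
        names = [n for n, z in zip(descriptor_names, zero) if z]
        logger.warning("zero-variance descriptors %s: scale set to 1", names)
        scale = np.where(zero, 1.0, scale)
    return ReferenceSpace(
        descriptor_names=tuple(descriptor_names),
        center=center,
        scale=scale,
        ea_ids=[a.id for a in eas],
        va_ids=[a.id for a in vas],
        ea_coords=(ea_mat - center) / scale,
        va_coords=(va_mat - center) / scale,
    )


def compute_nbh(space: ReferenceSpace, radius: float = DEFAULT_RADIUS) -> NeighborhoodModel:
    """Euclidean-ball membership of every VA in every EA neighborhood."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if space.va_coords.shape[0] and space.ea_coords.shape[0]:
        dist = cdist(space.va_coords, space.ea_coords)
        membership = dist <= radius
    else:
        membership = np.zeros(
            (space.va_coords.shape[0], space.ea_coords.shape[0]), dtype=bool
        )
    return NeighborhoodModel(
        radius=radius,
        ea_ids=list(space.ea_ids),
        va_ids=list(space.va_ids),
        membership=membership,
    )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def score_saturation(nbh: NeighborhoodModel) -> tuple[float, Optional[float], float, float]:
    """Coverage C, mean depth d_mean, density D and saturation S.

    ``NBH_O_VA`` (total VA-in-NBH incidences, i.e. the sum of m_i over
    in-NBH VAs) divided by n_N gives d_mean >= 1; D = 1 - 1/d_mean; S is the
    harmonic mean of C and D (0 when C + D = 0).
    """
    n_v = nbh.n_v
    if n_v == 0:
        raise ValueError("no VA population (n_V = 0)")
    m = nbh.multiplicity
    in_nbh = m > 0
    n_n = int(in_nbh.sum())
    c = n_n / n_v
    if n_n == 0:
        return 0.0, None, 0.0, 0.0
    nbh_o_va = int(m[in_nbh].sum())
    d_mean = nbh_o_va / n_n
    d = 1.0 - 1.0 / d_mean
    s = 0.0 if (c + d) == 0 else 2.0 * c * d / (c + d)
    return c, d_mean, d, s


def mean_pairwise_difference(values: Sequence[float]) -> float:
    """Mean absolute pairwise difference over a set of potencies."""
    pairs = list(itertools.combinations(values, 2))
    if not pairs:
        raise ValueError("need at least two values")
    return sum(abs(a - b) for a, b in pairs) / len(pairs)


def score_progression(
    nbh: NeighborhoodModel, potencies: Mapping[str, float]
) -> Optional[float]:
    """SAR progression P: weighted mean potency spread over shared VAs.

    Each VA contained in m_i > 1 neighborhoods contributes the mean absolute
    pairwise potency difference of its m_i EAs with weight 1/m_i; VAs in a
    single NBH carry zero weight.  Returns ``None`` when every weight is zero.
    """
    m = nbh.multiplicity
    num = 0.0
    den = 0.0
    for i in range(nbh.n_v):
        if m[i] <= 1:
            continue
        eas = nbh.members_of(i)
        vals = []
        for e in eas:
            if e not in potencies or potencies[e] is None:
                raise ValueError(f"missing potency for EA {e}")
            vals.append(float(potencies[e]))
        delta_bar = mean_pairwise_difference(vals)
        w = 1.0 / m[i]
        num += w * delta_bar
        den += w
    if den == 0.0:
        return None
    return num / den


def harmonic_mean(a: float, b: float) -> float:
    if a + b == 0:
        return 0.0
    return 2.0 * a * b / (a + b)


def is_defined(x: Optional[float]) -> bool:
    return x is not None and not (isinstance(x, float) and math.isnan(x))
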