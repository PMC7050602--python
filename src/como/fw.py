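"""Free-Wilson neighborhood detection, analog generation and potency prediction.

A Free-Wilson neighborhood (FW NBH) is a hub analog A with two MMP edges at
distinct substitution sites (A-B at s1, A-C at s2).  Applying both exchanges
to A defines a double-substituted target X which forms an MMP with B and with
C but not with A.  Under the additivity assumption the potency of X is

    pot(X) = pot(A) + [pot(B) - pot(A)] + [pot(C) - pot(A)]
           = pot(B) + pot(C) - pot(A)

and predictions for a target are averaged over all NBHs defining it.
Targets already present in the series are FW EAs (used to benchmark the
additive prediction); novel targets are FW VAs (design candidates).  The
saturation score N = 1 - n_FW_EA / n_FW_NBH quantifies how many NBHs exist
per FW EA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from como.chem import (
    PROVENANCE_VIRTUAL_FW,
    Analog,
    AnalogSeries,
    MMPEdge,
    MMPNetwork,
    recompose,
)

logger = logging.getLogger(__name__)


@dataclass
class FWNeighborhood:
    """Hub analog plus two single-site MMP edges defining a target analog."""

    hub: str
    edge_1: MMPEdge
    edge_2: MMPEdge
    target_table: dict[str, str]
    target_key: str
    target_exists: bool

    def __post_init__(self) -> None:
        if self.edge_1.site == self.edge_2.site:
            raise ValueError("FW NBH edges must be at distinct sites")
        # canonical ordering: edge_1 at the lexicographically smaller site
        if (self.edge_1.site or "") > (self.edge_2.site or ""):
            self.edge_1, self.edge_2 = self.edge_2, self.edge_1

    @property
    def partner_b(self) -> str:
        return self.edge_1.other(self.hub)

    @property
    def partner_c(self) -> str:
        return self.edge_2.other(self.hub)

    @property
    def sites(self) -> tuple[str, str]:
        return (self.edge_1.site, self.edge_2.site)


@dataclass
class FWPrediction:
    """Averaged additive potency prediction for one target analog."""

    target_key: str
    predicted_potency: float
    n_nbhs: int
    per_nbh_values: list[float]

    def __post_init__(self) -> None:
        if self.n_nbhs < 1:
            raise ValueError("a prediction requires at least one FW NBH")


def find_fw_nbhs(series: AnalogSeries, network: MMPNetwork) -> list[FWNeighborhood]:
    """Exhaustive FW-NBH search over the series' MMP network.

    Every hub with >= 2 incident edges at distinct sites contributes one NBH
    per unordered pair of such edges.  The target's substituent table is the
    hub's table with both exchanged substituents applied; chemically invalid
    recombinations are skipped with a log entry.
    """
    incident: dict[str, list[MMPEdge]] = {nid: [] for nid in network.nodes}
    for e in network.edges:
        if e.site is None:
            raise ValueError("network edges must carry series site labels")
        incident[e.analog_a].append(e)
        incident[e.analog_b].append(e)

    member_keys = series.member_keys
    nbhs: list[FWNeighborhood] = []
    for hub in sorted(incident):
        edges = sorted(incident[hub], key=lambda e: (e.site, e.pair))
        for e1, e2 in itertools.combinations(edges, 2):
            if e1.site == e2.site:
                continue
            hub_table = series.substituents[hub]
            table = dict(hub_table)
            table[e1.site] = e1.substituent_of(e1.other(hub))
            table[e2.site] = e2.substituent_of(e2.other(hub))
            try:
                key = recompose(series.core, table)
            except ValueError as exc:
                logger.warning(
                    "skipping FW NBH at hub %s (%s/%s): %s",
                    hub,
                    e1.site,
                    e2.site,
                    exc,
                )
                continue
            nbhs.append(
                FWNeighborhood(
                    hub=hub,
                    edge_1=e1,
                    edge_2=e2,
                    target_table=table,
                    target_key=key,
                    target_exists=key in member_keys,
                )
            )
    return nbhs


def generate_fw_vas(
    series: AnalogSeries, nbhs: Sequence[FWNeighborhood]
) -> tuple[list[Analog], list[Analog]]:
    """Materialize unique NBH targets, split into FW VAs and FW EAs.

    FW EAs are existing members re-identified as NBH targets; FW VAs are
    novel structures.  Output order is by canonical key (set semantics).
    """
    targets: dict[str, bool] = {}
    for nbh in nbhs:
        targets.setdefault(nbh.target_key, nbh.target_exists)

    by_key = {a.key: a for a in series.members}
    fw_eas: list[Analog] = []
    fw_vas: list[Analog] = []
    counter = 0
    for key in sorted(targets):
        if targets[key]:
            fw_eas.append(by_key[key])
        else:
            counter += 1
            fw_vas.append(
                Analog(
                    id=f"{series.series_id}-FWVA{counter:05d}",
                    smiles=key,
                    provenance=PROVENANCE_VIRTUAL_FW,
                )
            )
    return fw_vas, fw_eas


def fw_predict(
    target_key: str,
    nbhs: Sequence[FWNeighborhood],
    potencies: Mapping[str, float],
) -> FWPrediction:
    """Additive potency prediction for one target, averaged over its NBHs."""
    mine = [n for n in nbhs if n.target_key == target_key]
    if not mine:
        raise ValueError(f"no FW NBH covers target {target_key}")
    values = []
    for nbh in mine:
        for cid in (nbh.hub, nbh.partner_b, nbh.partner_c):
            if cid not in potencies or potencies[cid] is None:
                raise ValueError(f"missing potency for compound {cid}")
        pot_a = float(potencies[nbh.hub])
        pot_b = float(potencies[nbh.partner_b])
        pot_c = float(potencies[nbh.partner_c])
        values.append(pot_b + pot_c - pot_a)
    return FWPrediction(
        target_key=target_key,
        predicted_potency=sum(values) / len(values),
        n_nbhs=len(values),
        per_nbh_values=values,
    )


def virtualize_and_predict_eas(
    series: AnalogSeries, nbhs: Sequence[FWNeighborhood]
) -> list[tuple[FWPrediction, float]]:
    """Predict every FW EA from the NBHs in which it is the target.

    The target's own potency never enters its prediction (it is never part of
    its own NBH); B/C compounds retain their experimental potencies even when
    they are FW EAs elsewhere.  Returns (prediction, true potency) pairs.
    """
    potencies = series.potency_map()
    ea_keys = sorted({n.target_key for n in nbhs if n.target_exists})
    by_key = {a.key: a for a in series.members}
    out: list[tuple[FWPrediction, float]] = []
    for key in ea_keys:
        truth = by_key[key].potency
        if truth is None:
            logger.warning("FW EA %s has no measured potency, skipped", by_key[key].id)
            continue
        pred = fw_predict(key, nbhs, potencies)
        out.append((pred, truth))
    return out


def score_fw_saturation(n_fw_ea: int, n_fw_nbh: int) -> Optional[float]:
    """FW-NBH saturation score N = 1 - n_FW_EA / n_FW_NBH.

    ``n_fw_nbh`` counts the NBHs whose target is an FW EA.  Returns ``None``
    when no such NBH exists.
    """
    if n_fw_ea < 0 or n_fw_nbh < 0:
        raise ValueError("counts must be nonnegative")
    if n_fw_nbh == 0:
        return None
    if n_fw_ea > n_fw_nbh:
        raise ValueError("every FW EA occurs in at least one FW NBH")
    return 1.0 - n_fw_ea / n_fw_nbh


def fw_counts(nbhs: Sequence[FWNeighborhood]) -> tuple[int, int]:
    """(n_FW_EA, n_FW_NBH) with NBHs restricted to existing targets."""
    ea_nbhs = [n for n in nbhs if n.target_exists]
    return len({n.target_key for n in ea_nbhs}), len(ea_nbhs)
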