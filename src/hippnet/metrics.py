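"""Three-level descriptive network measures.

* Network level: intranetwork composite scores Cp (mean within-network edge
  weight) for the AHN and PHN, and the internetwork composite score Cpq
  (mean cross-network edge weight).
* Nodal level: weighted degree k_i, the sum of node i's edge weights to all
  other nodes of the joint 24-node network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ConnectivityMatrix, NetworkPartition

__all__ = ["CompositeScores", "NodalDegrees", "composite_scores", "nodal_degrees"]


@dataclass(frozen=True)
class CompositeScores:
    cp_ahn: float
    cp_phn: float
    cpq: float
    subject_id: str = ""


@dataclass(frozen=True)
class NodalDegrees:
    k: np.ndarray  # length-24, partition order
    subject_id: str = ""


def composite_scores(m: ConnectivityMatrix, partition: NetworkPartition | None = None) -> CompositeScores:
    """Mean edge weight within AHN, within PHN, and across the two networks.

    Cp = (1 / (Np (Np - 1))) * sum over ordered within-network pairs z_ij;
    Cpq = (1 / (Np Nq)) * sum over cross-network pairs z_ij.
    """
    part = partition or m.partition
    ia = part.network_indices("AHN")
    ip = part.network_indices("PHN")
    za = m.z[np.ix_(ia, ia)]
    zp = m.z[np.ix_(ip, ip)]
    zx = m.z[np.ix_(ia, ip)]
    na, np_ = len(ia), len(ip)
    cp_ahn = float(za.sum() / (na * (na - 1)))
    cp_phn = float(zp.sum() / (np_ * (np_ - 1)))
    cpq = float(zx.sum() / (na * np_))
    return CompositeScores(cp_ahn=cp_ahn, cp_phn=cp_phn, cpq=cpq, subject_id=m.subject_id)


def nodal_degrees(m: ConnectivityMatrix, per_network: bool = False) -> NodalDegrees:
    """Weighted degree k_i = sum_{j != i} z_ij.

    By default the sum runs over all 24 nodes of the joint network; with
    ``per_network`` it is restricted to nodes of i's own network.
    """
    if not per_network:
        k = m.z.sum(axis=1)
    else:
        networks = np.array([n[2] for n in m.partition.nodes])
        same = networks[:, None] == networks[None, :]
        k = (m.z * same).sum(axis=1)
    return NodalDegrees(k=np.asarray(k, dtype=float), subject_id=m.subject_id)
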