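"""Canonical resting-state network (RSN) labels and orderings.

The 11-network parcellation labels used throughout the package. The slot
ordering of RSN-level feature vectors is fixed by ``CANONICAL_NETWORKS``:
intra-network slots follow this order, inter-network slots follow the
row-major upper triangle of the same ordering.
"""

from __future__ import annotations

#: Fixed canonical ordering of the 11 resting-state networks.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "SM",
    "SM-lat",
    "VIS",
    "AUD",
    "DAN",
    "VAN",
    "CO",
    "DMN",
    "SAL",
    "FP",
    "SUB",
)

#: Networks treated as "sensory" for the primary-component sign convention.
SENSORY_NETWORKS: tuple[str, ...] = ("SM", "SM-lat", "VIS", "AUD")

#: Default signed per-network weights (sensory-like positive, higher-order
#: cognitive negative) used by the synthetic contrast presets.
DEFAULT_NETWORK_SIGNS: dict[str, float] = {
    "SM": 1.0,
    "SM-lat": 1.0,
    "VIS": 1.0,
    "AUD": 1.0,
    "DAN": 1.0,
    "VAN": 1.0,
    "CO": 1.0,
    "DMN": -1.0,
    "SAL": -1.0,
    "FP": -1.0,
    "SUB": -1.0,
}


def n_feature_slots(n_networks: int) -> int:
    """Number of RSN-level feature slots: ``n`` intra + ``n(n-1)/2`` inter."""
    return n_networks + n_networks * (n_networks - 1) // 2
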