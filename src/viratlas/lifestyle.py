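"""Family-level phage lifestyle calls from integrase carriage.

A family is called virulent when more than 95% of its complete vOTUs lack
an integrase, and temperate when at least half of all member vOTUs
(complete and incomplete) carry one.  Temperate takes precedence when both
rules fire, since integrase presence is positive evidence while absence can
reflect genome fragmentation.  Families with too few complete genomes stay
mixed_or_unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["LifestyleConfig", "LifestyleCall", "votu_has_integrase", "classify_family", "classify_families"]

VIRULENT = "virulent"
TEMPERATE = "temperate"
MIXED = "mixed_or_unknown"


@dataclass(frozen=True)
class LifestyleConfig:
    virulent_threshold: float = 0.95  # strict >, on complete vOTUs lacking integrase
    temperate_threshold: float = 0.50  # >=, on all vOTUs carrying integrase
    min_complete: int = 2

    def __post_init__(self):
        if not (0 < self.virulent_threshold < 1 and 0 < self.temperate_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.min_complete < 1:
            raise ValueError("min_complete must be >= 1")


@dataclass(frozen=True)
class LifestyleCall:
    family_id: str
    call: str
    f_virulent: float  # fraction of complete vOTUs lacking an integrase
    f_temperate: float  # fraction of all vOTUs carrying an integrase
    n_complete: int
    n_votus: int


def votu_has_integrase(gene_vogs: Iterable[str], integrase_vogs: set[str]) -> bool:
    """True iff any of the vOTU's genes falls in a curated integrase VOG."""
    return any(v in integrase_vogs for v in gene_vogs)


def classify_family(
    complete_flags: Sequence[bool],
    integrase_flags: Sequence[bool],
    config: LifestyleConfig | None = None,
    family_id: str = "",
) -> LifestyleCall:
    """Call one family from aligned per-vOTU completeness and integrase flags."""
    config = config or LifestyleConfig()
    if len(complete_flags) != len(integrase_flags) or not complete_flags:
        raise ValueError("need equal-length, non-empty flag vectors")
    n = len(complete_flags)
    complete_idx = [i for i, c in enumerate(complete_flags) if c]
    n_complete = len(complete_idx)
    f_t = sum(bool(f) for f in integrase_flags) / n
    f_v = (
        sum(not integrase_flags[i] for i in complete_idx) / n_complete
        if n_complete
        else float("nan")
    )
    if n_complete < config.min_complete:
        call = MIXED
    elif f_t >= config.temperate_threshold:
        call = TEMPERATE
    elif f_v > config.virulent_threshold:
        call = VIRULENT
    else:
        call = MIXED
    return LifestyleCall(family_id, call, f_v, f_t, n_complete, n)


def classify_families(
    members: pd.DataFrame,
    config: LifestyleConfig | None = None,
) -> pd.DataFrame:
    """Vectorised calls for a table with columns family/complete/integrase."""
    rows = []
    for fam, grp in members.groupby("family"):
        call = classify_family(
            grp["complete"].fillna(False).astype(bool).tolist(),
            grp["integrase"].astype(bool).tolist(),
            config,
            family_id=str(fam),
        )
        rows.append(call.__dict__)
    return pd.DataFrame(rows)
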