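"""Two-step ranked expression profiles and top/bottom-n signatures.

A drug's amplitude profile is ordered by an *effective* value that folds in
the detection calls: probes not flagged 'Present in a cell line' have their
average difference set to 0 before the descending sort, and the resulting
block of zeroed probes is then sub-sorted by the retained initial average
difference.  Absent probes therefore gather between the positive and negative
present probes, ordered among themselves by how strongly they appeared to
move.  The "optimal signature" is the top n and bottom n of that ordering
(n = 250 on full-size arrays).

Tie rule (the primary ordering keys leave it open): equal keys are broken by
probe-id lexicographic order, which keeps every ranking reproducible.  A
present probe whose value is exactly 0 was never "set to 0", so its sub-sort
key inside the zero block is 0 itself; id order applies among equals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["RankedProfile", "Signature", "rank_profile", "extract_signature"]


@dataclass
class RankedProfile:
    """Descending probe ordering of one amplitude profile (rank 1 = most up)."""

    drug_id: str
    cell_line: str
    probes: np.ndarray          # ordered probe ids
    effective: np.ndarray       # value used for ordering (0 where absent)
    initial: np.ndarray         # retained initial average difference
    _pos: dict = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.probes)

    def positions(self, query: Iterable[str]) -> np.ndarray:
        """0-based ranks of *query* probes; -1 for probes not in the profile."""
        if self._pos is None:
            self._pos = {p: i for i, p in enumerate(self.probes)}
        return np.fromiter((self._pos.get(p, -1) for p in query), dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "probe_id": self.probes,
            "rank": np.arange(1, len(self.probes) + 1),
            "effective_value": self.effective,
            "initial_value": self.initial,
        })


@dataclass(frozen=True)
class Signature:
    """Top-n (up) and bottom-n (down) probe sets of a ranked profile."""

    drug_id: str
    cell_line: str
    up: tuple[str, ...]
    down: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.up)


def rank_profile(
    profile: pd.Series,
    present: Iterable[str],
    drug_id: str = "",
    cell_line: str = "",
) -> RankedProfile:
    """Order a profile by the two-step detection-call-aware rule.

    Step 1 zeroes the average difference of probes outside *present*; step 2
    sorts all probes descending by that effective value; step 3 sub-sorts the
    zeroed block descending by the initial average difference.
    """
    probes = profile.index.to_numpy(dtype=object)
    initial = profile.to_numpy(dtype=float)
    present_mask = profile.index.isin(set(present))
    effective = np.where(present_mask, initial, 0.0)
    # sub-key is live only inside the zero block; a present probe at exactly 0
    # keeps sub-key 0 (it was never zeroed).
    zero_block = effective == 0.0
    subkey = np.where(zero_block & ~present_mask, initial, 0.0)
    order = np.lexsort((probes, -subkey, -effective))
    return RankedProfile(
        drug_id=drug_id,
        cell_line=cell_line,
        probes=probes[order],
        effective=effective[order],
        initial=initial[order],
    )


def extract_signature(ranked: RankedProfile, n: int = 250) -> Signature:
    """Top-n and bottom-n probe ids of a ranked profile."""
    if n < 1:
        raise ValueError("signature size n must be >= 1")
    if 2 * n > len(ranked):
        raise ValueError(
            f"profile has {len(ranked)} probes; need at least {2 * n} for n={n}"
        )
    return Signature(
        drug_id=ranked.drug_id,
        cell_line=ranked.cell_line,
        up=tuple(ranked.probes[:n]),
        down=tuple(ranked.probes[-n:]),
    )
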