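"""Affiliation sequences and edit-distance network similarity.

Raw community labels are arbitrary, so a partition is first rewritten
as a canonical *affiliation sequence*: walk the channels in a fixed
order (lexicographic by channel id across all trials of a session) and
give the first community encountered the symbol ``A``, the second
``B``, and so on.  Channels inactive in a trial receive the reserved
symbol ``-`` so that sequences keep a constant length across trials.
Two partitions that are identical up to a label permutation then map
to the identical string, and the Levenshtein edit distance between the
strings of consecutive trials measures how much the functional network
reorganised:

    similarity(a, b) = 1 - levenshtein(a, b) / max(|a|, |b|)
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import AnalysisError, ValidationError

#: Canonical community symbols, assigned in order of first appearance.
SYMBOLS = string.ascii_uppercase + string.ascii_lowercase + string.digits
#: Reserved symbol for channels absent from the partition (inactive).
INACTIVE_SYMBOL = "-"


@dataclass(frozen=True)
class AffiliationSequence:
    node_order: tuple
    labels: str

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.node_order):
            raise ValidationError("sequence length must equal node count")

    def __str__(self) -> str:
        return self.labels


def affiliation_sequence(
    membership: Mapping, node_order: Sequence[str]
) -> AffiliationSequence:
    """Canonical symbol sequence for a partition under a fixed node order.

    ``node_order`` must cover every node of the partition; nodes in the
    order but absent from the partition are marked inactive.
    """
    order = tuple(node_order)
    missing = set(membership) - set(order)
    if missing:
        raise ValidationError(f"node_order misses partition nodes: {sorted(missing)[:5]}")
    symbol_of: dict = {}
    out = []
    for node in order:
        if node not in membership:
            out.append(INACTIVE_SYMBOL)
            continue
        c = membership[node]
        if c not in symbol_of:
            if len(symbol_of) >= len(SYMBOLS):
                raise ValidationError("more communities than available symbols")
            symbol_of[c] = SYMBOLS[len(symbol_of)]
        out.append(symbol_of[c])
    return AffiliationSequence(node_order=order, labels="".join(out))


def levenshtein(a: Sequence, b: Sequence) -> int:
    """Unit-cost edit distance (insert/delete/substitute) between two
    symbol sequences, by the classic two-row dynamic programme."""
    a, b = list(a), list(b)
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # delete
                cur[j - 1] + 1,  # insert
                prev[j - 1] + (ca != cb),  # substitute
            )
        prev = cur
    return prev[-1]


def network_similarity(seq_a, seq_b) -> float:
    """Normalised edit similarity in [0, 1] between two trials'
    affiliation sequences (1 iff the canonical sequences are equal)."""
    a = str(seq_a) if isinstance(seq_a, AffiliationSequence) else "".join(seq_a)
    b = str(seq_b) if isinstance(seq_b, AffiliationSequence) else "".join(seq_b)
    n = max(len(a), len(b))
    if n == 0:
        raise AnalysisError("similarity undefined for two empty sequences")
    return 1.0 - levenshtein(a, b) / n
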