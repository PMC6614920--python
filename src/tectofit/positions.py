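"""Position labels for the 23-position loop-receptor signature.

The THF loop-receptor motif is described on a fixed positional scheme running
5'->3' over the loop and the 3' receptor strand (positions "1" through "23").
Variants may delete a position (the label is simply absent from the variant)
or insert a residue between two canonical positions; insertions carry
fractional labels such as "6.1" (a residue between positions 6 and 7).
Labels are plain strings; this module supplies validation and the total
ordering "6" < "6.1" < "7".
"""

from __future__ import annotations

import re

__all__ = ["is_valid_label", "label_key", "sort_labels", "canonical_labels"]

_LABEL_RE = re.compile(r"^([0-9]+)(?:\.([0-9]+))?$")


def is_valid_label(label: str) -> bool:
    """True if *label* is a well-formed position label ("7", "6.1", ...)."""
    return bool(_LABEL_RE.match(label))


def label_key(label: str) -> tuple[int, int]:
    """Sort key placing insertion labels between their flanking positions.

    >>> label_key("6") < label_key("6.1") < label_key("7")
    True
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"malformed position label: {label!r}")
    major, minor = m.groups()
    return int(major), int(minor) if minor is not None else 0


def sort_labels(labels) -> list[str]:
    """Sorted list of unique labels under the positional ordering."""
    return sorted(set(labels), key=label_key)


def canonical_labels(n: int = 23) -> list[str]:
    """The default label set "1".."23" of the full signature."""
    return [str(i) for i in range(1, n + 1)]
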