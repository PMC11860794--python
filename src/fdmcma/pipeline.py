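"""End-to-end conveniences: raw signal -> normalized -> decomposed -> data matrix."""

from __future__ import annotations

from .features import DataMatrix, build_data_matrix
from .fdm import Signal, decompose, normalize_signal

__all__ = ["process_signal", "process_signals"]


def process_signal(raw: Signal, variant: str = "D") -> DataMatrix:
    """Normalize, decompose and stack one signal into its data matrix."""
    s = normalize_signal(raw)
    return build_data_matrix(s, decompose(s), variant=variant)


def process_signals(raws: list[Signal], variant: str = "D") -> list[DataMatrix]:
    """:func:`process_signal` over a list (kept explicit for progress hooks)."""
    return [process_signal(r, variant=variant) for r in raws]
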