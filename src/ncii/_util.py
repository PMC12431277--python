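"""Small shared helpers."""

from __future__ import annotations


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 levels.

    The convention used throughout: "***" for p < 0.001, "**" for
    p < 0.01, "*" for p < 0.05, empty string otherwise.
    """
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
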