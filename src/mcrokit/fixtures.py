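"""Access to the bundled sample cards.

Two sample model cards ship with the package: ``pci`` (adverse endpoint
prediction for percutaneous coronary intervention) and ``hiv``
(social-network based HIV status prediction).  Titles and section layout
mirror the published samples; body prose is short placeholder text.
"""

from __future__ import annotations

from importlib import resources

from .card import ModelCard, read_card

__all__ = ["SAMPLE_CARDS", "sample_card_text", "load_sample_card"]

SAMPLE_CARDS = ("pci", "hiv")


def sample_card_text(name: str) -> str:
    """Raw card document for a bundled sample (``pci`` or ``hiv``)."""
    if name not in SAMPLE_CARDS:
        raise KeyError(f"unknown sample card {name!r}; have {SAMPLE_CARDS}")
    ref = resources.files("mcrokit").joinpath(f"data/cards/{name}.yaml")
    return ref.read_text(encoding="utf-8")


def load_sample_card(name: str) -> ModelCard:
    """Parsed and validated bundled sample card."""
    return read_card(sample_card_text(name))
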