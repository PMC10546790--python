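"""Access to the shipped network definition files."""

from __future__ import annotations

from importlib import resources

from .network import Network, parse_network

__all__ = ["fixture_text", "load_fixture", "FIXTURES"]

FIXTURES = (
    "toy_linear",
    "toy_diamond",
    "toy_condensation",
    "toy_exchange",
    "toy_scramble",
    "toy_midsize",
    "lemna_core_A",
    "lemna_core_B",
    "lemna_core_C",
)


def fixture_text(name: str) -> str:
    ref = resources.files("lemnaflux.data.networks") / f"{name}.tsv"
    return ref.read_text()


def load_fixture(name: str) -> Network:
    """Parse one of the shipped network fixtures by name."""
    return parse_network(fixture_text(name))
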