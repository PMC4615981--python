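import pytest

from discomorb import (
    Direction,
    Disease,
    PropensityScale,
    ProteinRecord,
    ProteinSet,
    ScaleRegistry,
    default_registry,
)


def uniform_scale(value: float, name: str = "const",
                  feature_class: str = "disorder") -> PropensityScale:
    from discomorb import CANONICAL
    return PropensityScale(name, feature_class,
                           {a: value for a in CANONICAL})


def two_letter_scale(av: float, vv: float, name: str = "toy",
                     feature_class: str = "disorder",
                     normalized: bool = False) -> PropensityScale:
    """Scale distinguishing A and V; all other residues get (av+vv)/2."""
    from discomorb import CANONICAL
    values = {a: (av + vv) / 2.0 for a in CANONICAL}
    values["A"], values["V"] = av, vv
    return PropensityScale(name, feature_class, values,
                           normalized=normalized)


@pytest.fixture(scope="session")
def registry() -> ScaleRegistry:
    return default_registry()


@pytest.fixture
def record_factory():
    def make(seq: str, pid: str = "p1", gene: str | None = None):
        return ProteinRecord(id=pid, gene=gene or pid, sequence=seq)
    return make


@pytest.fixture
def set_factory(record_factory):
    def make(seqs: list[str], name: str = "S",
             disease: Disease = Disease.OTHER,
             direction: Direction = Direction.NA):
        records = [record_factory(s, pid=f"{name.lower()}{i}")
                   for i, s in enumerate(seqs, 1)]
        return ProteinSet(name=name, disease=disease, direction=direction,
                          records=records)
    return make
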