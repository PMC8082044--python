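import numpy as np
import pytest
from hypothesis import settings

from crispamp.targets import make_target

settings.register_profile("crispamp", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("crispamp")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _embed_guide(rng, length, proto_len=20, guide_start=100, pam="AGG"):
    """Random amplicon with an exact protospacer+NGG planted at a known
    offset; regenerated until the placement is unique."""
    from crispamp.targets import locate_guide, GuideSpec, CAS9
    while True:
        seq = list(rng.choice(list("ACGT"), size=length))
        proto = "".join(rng.choice(list("ACGT"), size=proto_len))
        seq[guide_start:guide_start + proto_len] = proto
        seq[guide_start + proto_len:guide_start + proto_len + 3] = pam
        ref = "".join(seq)
        try:
            s, strand = locate_guide(ref, GuideSpec(proto, CAS9))
        except Exception:
            continue
        if s == guide_start and strand == "+":
            return ref, proto


@pytest.fixture
def cas9_target(rng):
    """A 250-bp Cas9 target: protospacer at [100,120), PAM at [120,123),
    blunt cut bond 117, default window [109,125)."""
    ref, proto = _embed_guide(rng, 250)
    return make_target("tgt", ref, proto, enzyme="cas9")
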