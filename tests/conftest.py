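import numpy as np
import pytest

from sonoquant import (
    PhantomSpec,
    SessionPlan,
    build_emitter_array,
    inject_session,
    make_head_phantom,
)


@pytest.fixture(scope="session")
def array():
    return build_emitter_array()


@pytest.fixture(scope="session")
def phantom():
    """Small 1.5-mm phantom shared by scoring/synth tests."""
    spec = PhantomSpec(shape=(96, 96, 96), seed=7)
    pre, seg, brain = make_head_phantom(spec)
    return pre, seg, brain


@pytest.fixture(scope="session")
def mixed_session(array, phantom):
    """One session with a mixed per-emitter plan: grades 2,2,2,3,3,3,1,0,0."""
    pre, seg, _ = phantom
    plan = SessionPlan(
        patterns=(
            "gray", "gray", "gray",
            "gray_white", "gray_white", "gray_white",
            "subarachnoid", "none", "none",
        ),
        e0=0.30,
        noise_sigma=0.005,
        seed=11,
    )
    pre, post = inject_session(pre, seg, array, plan)
    return pre, post, seg, plan
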