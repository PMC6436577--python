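import numpy as np
import pytest
from hypothesis import settings

from nsctfuse.fusion import FusionConfig
from nsctfuse.phantoms import PhantomSpec, make_pair
from nsctfuse.sfla import SFLAConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_sfla(seed: int = 0, **overrides) -> SFLAConfig:
    """Minimal but structurally complete SFLA budget for fast tests."""
    lower = np.array([0.01, 0.0, 1.0])
    upper = np.array([1.0, 1.0, 50.0])
    kwargs = dict(
        pop_size=4,
        n_memeplexes=2,
        memeplex_size=2,
        local_steps=2,
        shuffles=2,
        lower=lower,
        upper=upper,
        s_max=(upper - lower) / 2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SFLAConfig(**kwargs)


def tiny_fusion_config(seed: int = 0, **overrides) -> FusionConfig:
    kwargs = dict(
        nsct_spec=(1, (1,)),
        pcnn_iterations=5,
        sfla_config=tiny_sfla(seed),
        seed=seed,
    )
    kwargs.update(overrides)
    return FusionConfig(**kwargs)


@pytest.fixture
def small_pair():
    """A 32x32 registered phantom pair."""
    return make_pair(PhantomSpec(size=(32, 32), seed=11))


def mirror_index(i: int, n: int) -> int:
    """scipy.ndimage mode='mirror' index reflection (no edge repeat)."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = i % period
    return i if i < n else period - i


@pytest.fixture
def scalar_pcnn_oracle():
    """Naive scalar-loop PCNN, independent of the vectorized engine."""

    def run(stimulus, alpha_theta, beta, v_theta, iterations, w):
        s = np.asarray(stimulus, dtype=float)
        m, n = s.shape
        km, kn = w.shape
        cy, cx = km // 2, kn // 2
        decay = float(np.exp(-alpha_theta))
        y = [[0.0] * n for _ in range(m)]
        theta = [[0.0] * n for _ in range(m)]
        counts = [[0] * n for _ in range(m)]
        for _ in range(iterations):
            if beta == 0.0:
                u = [[s[i, j] for j in range(n)] for i in range(m)]
            else:
                link = [[0.0] * n for _ in range(m)]
                for i in range(m):
                    for j in range(n):
                        acc = 0.0
                        for di in range(km):
                            for dj in range(kn):
                                # true convolution: kernel flipped
                                ii = mirror_index(i - (di - cy), m)
                                jj = mirror_index(j - (dj - cx), n)
                                acc += w[di, dj] * y[ii][jj]
                        link[i][j] = acc
                u = [
                    [s[i, j] * (1.0 + beta * link[i][j]) for j in range(n)]
                    for i in range(m)
                ]
            for i in range(m):
                for j in range(n):
                    theta[i][j] *= decay
                    if u[i][j] > theta[i][j]:
                        y[i][j] = 1.0
                        theta[i][j] += v_theta
                        counts[i][j] += 1
                    else:
                        y[i][j] = 0.0
        return np.array(counts)

    return run
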