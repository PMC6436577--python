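"""Sub-band fusion rules and the end-to-end SPECT/CT fusion pipeline.

The proposed method: split the functional (SPECT-like) image into I/H/S,
decompose its intensity and the anatomical (CT-like) image with the NSCT,
fuse every matching sub-band pair by a PCNN coefficient-selection rule
whose three neuron parameters are tuned per band by the shuffled
frog-leaping optimizer, reconstruct the fused intensity and invert the
IHS transform.  Four baselines ship for comparison: plain IHS intensity
substitution, NSCT with max-|coefficient| highs / averaged low, a 2-level
DWT with the same max/average rule, and NSCT+PCNN with fixed parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml
from scipy import ndimage

from . import sfla
from .errors import ConfigurationError, StructureError
from .ihs import ihs_to_rgb_with_count, rgb_to_ihs
from .image_io import (
    UNIT,
    ColorImage,
    RasterImage,
    check_registered_pair,
    normalize_intensity,
)
from .metrics import MetricsReport, entropy, evaluate_all, mean_gradient, quantize_gray
from .nsct import (
    DEFAULT_FILTER_FAMILY,
    DEFAULT_SPEC,
    NSCTPyramid,
    build_filter_bank,
    nsct_decompose,
    nsct_reconstruct,
)
from .pcnn import FiringMap, PCNNParams, default_linking_kernel, run_pcnn

BASELINE_METHODS = ("ihs", "nsct_fl", "dwt", "nsct_pcnn")
FITNESS_NAMES = ("entropy", "mean_gradient", "entropy_gradient")

#: Fixed neuron parameters for the untuned NSCT+PCNN baseline: mid-box
#: values of the default search ranges.
FIXED_PCNN = (0.3, 0.2, 20.0)


def default_sfla_config(seed: int = 0) -> sfla.SFLAConfig:
    """Desk-scale SFLA budget over the PCNN parameter box.

    Bounds: alpha_theta in [0.01, 1], beta in [0, 1], V_theta in [1, 50]
    (typical simplified-PCNN operating ranges).  S_max is half the box
    width per coordinate.
    """
    lower = np.array([0.01, 0.0, 1.0])
    upper = np.array([1.0, 1.0, 50.0])
    return sfla.SFLAConfig(
        pop_size=10,
        n_memeplexes=2,
        memeplex_size=5,
        local_steps=5,
        shuffles=5,
        lower=lower,
        upper=upper,
        s_max=(upper - lower) / 2.0,
        seed=seed,
    )


@dataclass(frozen=True, eq=False)
class FusionConfig:
    """Every free choice of the pipeline, with documented defaults."""

    nsct_spec: tuple[int, tuple[int, ...]] = DEFAULT_SPEC
    filter_family: str = DEFAULT_FILTER_FAMILY
    pcnn_iterations: int = 100
    linking_kernel: np.ndarray = field(default_factory=default_linking_kernel)
    sfla_config: sfla.SFLAConfig = field(default_factory=default_sfla_config)
    fitness_name: str = "entropy"
    tie_policy: str = "mean"
    granularity: str = "per-band"          # or "shared"
    low_rule: str = "sfla_pcnn"            # or "regional_energy"
    inject_fixed_params: bool = False
    fixed_pcnn: tuple[float, float, float] = FIXED_PCNN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fitness_name not in FITNESS_NAMES:
            raise ConfigurationError(
                f"unknown fitness {self.fitness_name!r}; supported: {FITNESS_NAMES}"
            )
        if self.tie_policy not in ("mean", "first", "second"):
            raise ConfigurationError(f"unknown tie policy {self.tie_policy!r}")
        if self.granularity not in ("per-band", "shared"):
            raise ConfigurationError(f"unknown granularity {self.granularity!r}")
        if self.low_rule not in ("sfla_pcnn", "regional_energy"):
            raise ConfigurationError(f"unknown low-band rule {self.low_rule!r}")
        lo, hi = self.sfla_config.lower, self.sfla_config.upper
        if lo[0] <= 0 or lo[2] <= 0 or lo[1] < 0:
            raise ConfigurationError(
                "bounds must be positive for alpha_theta and V_theta, "
                "non-negative for beta"
            )

    def make_params(self, x: np.ndarray | tuple) -> PCNNParams:
        a, b, v = (float(t) for t in x)
        return PCNNParams(
            alpha_theta=a,
            beta=b,
            v_theta=v,
            iterations=self.pcnn_iterations,
            linking_kernel=self.linking_kernel,
        )

    def to_dict(self) -> dict:
        c = self.sfla_config
        return {
            "nsct_spec": [self.nsct_spec[0], list(self.nsct_spec[1])],
            "filter_family": self.filter_family,
            "pcnn_iterations": self.pcnn_iterations,
            "linking_kernel": np.asarray(self.linking_kernel).tolist(),
            "sfla": {
                "pop_size": c.pop_size,
                "n_memeplexes": c.n_memeplexes,
                "memeplex_size": c.memeplex_size,
                "local_steps": c.local_steps,
                "shuffles": c.shuffles,
                "lower": c.lower.tolist(),
                "upper": c.upper.tolist(),
                "s_max": np.asarray(c.s_max).tolist(),
                "per_coordinate_rand": c.per_coordinate_rand,
            },
            "fitness_name": self.fitness_name,
            "tie_policy": self.tie_policy,
            "granularity": self.granularity,
            "low_rule": self.low_rule,
            "inject_fixed_params": self.inject_fixed_params,
            "fixed_pcnn": list(self.fixed_pcnn),
            "seed": self.seed,
        }


def config_from_dict(data: dict) -> FusionConfig:
    """Build a :class:`FusionConfig` from a (partial) plain dict."""
    data = dict(data or {})
    seed = int(data.pop("seed", 0))
    kwargs: dict = {"seed": seed}
    if "nsct_spec" in data:
        j, dirs = data.pop("nsct_spec")
        kwargs["nsct_spec"] = (int(j), tuple(int(d) for d in dirs))
    for key in ("filter_family", "pcnn_iterations", "fitness_name", "tie_policy",
                "granularity", "low_rule", "inject_fixed_params"):
        if key in data:
            kwargs[key] = data.pop(key)
    if "linking_kernel" in data:
        kwargs["linking_kernel"] = np.asarray(data.pop("linking_kernel"), dtype=float)
    if "fixed_pcnn" in data:
        kwargs["fixed_pcnn"] = tuple(float(v) for v in data.pop("fixed_pcnn"))
    sfla_over = data.pop("sfla", {})
    base = default_sfla_config(seed)
    if sfla_over:
        merged = {
            "pop_size": base.pop_size,
            "n_memeplexes": base.n_memeplexes,
            "memeplex_size": base.memeplex_size,
            "local_steps": base.local_steps,
            "shuffles": base.shuffles,
            "lower": base.lower,
            "upper": base.upper,
            "s_max": base.s_max,
            "per_coordinate_rand": base.per_coordinate_rand,
        }
        merged.update(sfla_over)
        if "lower" in sfla_over or "upper" in sfla_over:
            lo = np.asarray(merged["lower"], dtype=float)
            hi = np.asarray(merged["upper"], dtype=float)
            merged["lower"], merged["upper"] = lo, hi
            if "s_max" not in sfla_over:
                merged["s_max"] = (hi - lo) / 2.0
        base = sfla.SFLAConfig(seed=seed, **merged)
    kwargs["sfla_config"] = base
    if data:
        raise ConfigurationError(f"unknown config keys: {sorted(data)}")
    return FusionConfig(**kwargs)


def load_config(path) -> FusionConfig:
    """Read a YAML configuration file (missing keys fall back to defaults)."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


@dataclass
class FusedResult:
    """Output of one fusion run."""

    fused: ColorImage
    intensity: RasterImage
    chosen_params: dict[str, tuple[float, float, float]]
    metrics: MetricsReport
    provenance: dict


# ---------------------------------------------------------------------------
# sub-band rules
# ---------------------------------------------------------------------------

def pcnn_activity(band: np.ndarray, params: PCNNParams) -> FiringMap:
    """Firing counts of a sub-band: stimulus is |band| min-max normalized.

    High-frequency coefficients are signed; magnitude is what measures
    activity, so the map is invariant to a global sign flip of the band.
    """
    stim, _, _ = normalize_intensity(RasterImage(np.abs(band), (0.0, np.inf)))
    return run_pcnn(stim.pixels, params)


def _tie_fuse(
    band_a: np.ndarray,
    band_b: np.ndarray,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    tie_policy: str,
) -> np.ndarray:
    if tie_policy == "mean":
        tie = (band_a + band_b) / 2.0
    elif tie_policy == "first":
        tie = band_a
    else:
        tie = band_b
    return np.where(counts_a > counts_b, band_a, np.where(counts_b > counts_a, band_b, tie))


def fuse_bands_pcnn(
    band_a: np.ndarray,
    band_b: np.ndarray,
    params: PCNNParams,
    tie_policy: str = "mean",
) -> np.ndarray:
    """Per pixel, keep the coefficient whose PCNN fires strictly more often.

    Ties take the policy (default: mean of the two coefficients, which makes
    self-fusion an exact identity).
    """
    if band_a.shape != band_b.shape:
        raise StructureError(f"band shapes differ: {band_a.shape} vs {band_b.shape}")
    ca = pcnn_activity(band_a, params).counts
    cb = pcnn_activity(band_b, params).counts
    return _tie_fuse(band_a, band_b, ca, cb, tie_policy)


def _fitness_value(fused_band: np.ndarray, fitness_name: str) -> float:
    levels = quantize_gray(fused_band)  # min-max remap to 8-bit integers
    if fitness_name == "entropy":
        return entropy(levels.astype(float))
    if fitness_name == "mean_gradient":
        return mean_gradient(levels.astype(float))
    # entropy_gradient: equal-weight blend of both, each on a [0, 1] scale
    return 0.5 * entropy(levels.astype(float)) / 8.0 + 0.5 * mean_gradient(
        levels.astype(float)
    ) / 255.0


def band_fitness(
    params: PCNNParams,
    band_a: np.ndarray,
    band_b: np.ndarray,
    fitness_name: str = "entropy",
    tie_policy: str = "mean",
) -> float:
    """Quality of the fused band these parameters would produce.

    Default: information entropy of the fused band remapped to 8-bit.  The
    optimized objective is a documented design choice (alternatives:
    ``mean_gradient``, ``entropy_gradient``).
    """
    fused = fuse_bands_pcnn(band_a, band_b, params, tie_policy)
    return _fitness_value(fused, fitness_name)


def _band_items(pyr: NSCTPyramid) -> list[tuple[str, np.ndarray]]:
    items = [("low", pyr.low)]
    for j, bands in enumerate(pyr.levels):
        for k, b in enumerate(bands):
            items.append((f"level{j + 1}_dir{k}", b))
    return items


def _regional_energy_fuse(band_a: np.ndarray, band_b: np.ndarray) -> np.ndarray:
    """Select the coefficient with larger 3x3 regional average energy."""
    ea = ndimage.uniform_filter(band_a**2, size=3, mode="mirror")
    eb = ndimage.uniform_filter(band_b**2, size=3, mode="mirror")
    tie = (band_a + band_b) / 2.0
    return np.where(ea > eb, band_a, np.where(eb > ea, band_b, tie))


def fuse_pyramids(
    pyr_a: NSCTPyramid,
    pyr_b: NSCTPyramid,
    cfg: FusionConfig,
) -> tuple[NSCTPyramid, dict[str, tuple[float, float, float]], dict[str, sfla.OptimizeResult]]:
    """Fuse two pyramids band by band with SFLA-tuned PCNN selection.

    Returns the fused pyramid, the chosen (alpha_theta, beta, V_theta) per
    band, and the per-band optimizer results (for auditing dominance and
    initial populations).  ``cfg.granularity == "shared"`` runs one
    optimization whose fitness is the mean band fitness and reuses the
    winner everywhere.
    """
    if pyr_a.spec != pyr_b.spec:
        raise StructureError(f"pyramid specs differ: {pyr_a.spec} vs {pyr_b.spec}")
    items_a = _band_items(pyr_a)
    items_b = _band_items(pyr_b)
    names = [n for n, _ in items_a]
    pairs = {n: (a, b) for (n, a), (_, b) in zip(items_a, items_b)}

    base_sfla = cfg.sfla_config
    if cfg.inject_fixed_params:
        base_sfla = dataclasses.replace(
            base_sfla, inject=(np.asarray(cfg.fixed_pcnn, dtype=float),)
        )
    band_seeds = np.random.SeedSequence(base_sfla.seed).generate_state(
        len(names) + 1
    ) % (2**31)

    def make_fitness(band_names: list[str]) -> Callable[[np.ndarray], float]:
        def fn(x: np.ndarray) -> float:
            params = cfg.make_params(x)
            vals = [
                band_fitness(params, *pairs[n], fitness_name=cfg.fitness_name,
                             tie_policy=cfg.tie_policy)
                for n in band_names
            ]
            return float(np.mean(vals))

        return fn

    chosen: dict[str, tuple[float, float, float]] = {}
    results: dict[str, sfla.OptimizeResult] = {}
    opt_names = list(names)
    if cfg.low_rule == "regional_energy":
        opt_names.remove("low")

    if cfg.granularity == "shared":
        shared_cfg = dataclasses.replace(base_sfla, seed=int(band_seeds[-1]))
        res = sfla.optimize(make_fitness(opt_names), shared_cfg)
        for n in opt_names:
            chosen[n] = tuple(float(v) for v in res.best.position)
            results[n] = res
    else:
        for i, n in enumerate(opt_names):
            cfg_i = dataclasses.replace(base_sfla, seed=int(band_seeds[i]))
            res = sfla.optimize(make_fitness([n]), cfg_i)
            chosen[n] = tuple(float(v) for v in res.best.position)
            results[n] = res

    def fuse_one(name: str) -> np.ndarray:
        a, b = pairs[name]
        if name == "low" and cfg.low_rule == "regional_energy":
            return _regional_energy_fuse(a, b)
        return fuse_bands_pcnn(a, b, cfg.make_params(chosen[name]), cfg.tie_policy)

    fused_low = fuse_one("low")
    fused_levels = tuple(
        tuple(fuse_one(f"level{j + 1}_dir{k}") for k in range(len(bands)))
        for j, bands in enumerate(pyr_a.levels)
    )
    fused = NSCTPyramid(low=fused_low, levels=fused_levels, spec=pyr_a.spec)
    return fused, chosen, results


def _fixed_param_fuse_pyramids(
    pyr_a: NSCTPyramid, pyr_b: NSCTPyramid, cfg: FusionConfig
) -> tuple[NSCTPyramid, dict[str, tuple[float, float, float]]]:
    """NSCT+PCNN baseline: the same selection rule with fixed parameters."""
    if pyr_a.spec != pyr_b.spec:
        raise StructureError(f"pyramid specs differ: {pyr_a.spec} vs {pyr_b.spec}")
    params = cfg.make_params(cfg.fixed_pcnn)
    fuse = lambda a, b: fuse_bands_pcnn(a, b, params, cfg.tie_policy)  # noqa: E731
    fused = NSCTPyramid(
        low=fuse(pyr_a.low, pyr_b.low),
        levels=tuple(
            tuple(fuse(a, b) for a, b in zip(la, lb))
            for la, lb in zip(pyr_a.levels, pyr_b.levels)
        ),
        spec=pyr_a.spec,
    )
    chosen = {n: cfg.fixed_pcnn for n, _ in _band_items(pyr_a)}
    return fused, chosen


def _max_avg_fuse_pyramids(pyr_a: NSCTPyramid, pyr_b: NSCTPyramid) -> NSCTPyramid:
    """Max-|coefficient| high bands, averaged low band (the FL rule)."""
    if pyr_a.spec != pyr_b.spec:
        raise StructureError(f"pyramid specs differ: {pyr_a.spec} vs {pyr_b.spec}")
    return NSCTPyramid(
        low=(pyr_a.low + pyr_b.low) / 2.0,
        levels=tuple(
            tuple(np.where(np.abs(a) >= np.abs(b), a, b) for a, b in zip(la, lb))
            for la, lb in zip(pyr_a.levels, pyr_b.levels)
        ),
        spec=pyr_a.spec,
    )


# ---------------------------------------------------------------------------
# end-to-end pipelines
# ---------------------------------------------------------------------------

def _finish(
    i_prime: np.ndarray,
    triple,
    chosen: dict,
    cfg: FusionConfig | None,
    method: str,
    seed: int,
) -> FusedResult:
    fused_rgb, n_clipped = ihs_to_rgb_with_count(i_prime, triple.h, triple.s)
    intensity = RasterImage(np.clip(i_prime, 0.0, 1.0), UNIT)
    report = evaluate_all(intensity)
    return FusedResult(
        fused=fused_rgb,
        intensity=intensity,
        chosen_params=chosen,
        metrics=report,
        provenance={
            "method": method,
            "seed": seed,
            "clipped_samples": n_clipped,
            "config": cfg.to_dict() if cfg is not None else None,
        },
    )


def fuse_spect_ct(
    spect: ColorImage, ct: RasterImage, cfg: FusionConfig | None = None
) -> FusedResult:
    """The proposed pipeline: IHS -> NSCT -> SFLA+PCNN fusion -> inverses."""
    cfg = cfg or FusionConfig()
    check_registered_pair(spect, ct)
    triple = rgb_to_ihs(spect)
    ct_unit = ct.to_unit()
    bank = build_filter_bank(cfg.filter_family)
    pyr_a = nsct_decompose(triple.i, cfg.nsct_spec, bank)
    pyr_b = nsct_decompose(ct_unit, cfg.nsct_spec, bank)
    fused_pyr, chosen, _ = fuse_pyramids(pyr_a, pyr_b, cfg)
    i_prime = nsct_reconstruct(fused_pyr, bank)
    return _finish(i_prime, triple, chosen, cfg, "proposed", cfg.seed)


def baseline_fuse(
    spect: ColorImage,
    ct: RasterImage,
    method: str,
    cfg: FusionConfig | None = None,
) -> FusedResult:
    """One of the four comparison methods: ihs, nsct_fl, dwt, nsct_pcnn."""
    cfg = cfg or FusionConfig()
    if method not in BASELINE_METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; supported: {list(BASELINE_METHODS)}"
        )
    check_registered_pair(spect, ct)
    triple = rgb_to_ihs(spect)
    ct_unit = ct.to_unit()

    if method == "ihs":
        return _finish(ct_unit.pixels, triple, {}, cfg, method, cfg.seed)

    if method == "dwt":
        from . import wavelet

        approx_a, det_a = wavelet.haar_decompose(triple.i.pixels, levels=2)
        approx_b, det_b = wavelet.haar_decompose(ct_unit.pixels, levels=2)
        approx = (approx_a + approx_b) / 2.0
        detail = []
        for (lla, da, sha), (_, db, _) in zip(det_a, det_b):
            fused_d = tuple(
                np.where(np.abs(a) >= np.abs(b), a, b) for a, b in zip(da, db)
            )
            detail.append((lla, fused_d, sha))
        i_prime = wavelet.haar_reconstruct(approx, detail)
        return _finish(i_prime, triple, {}, cfg, method, cfg.seed)

    bank = build_filter_bank(cfg.filter_family)
    pyr_a = nsct_decompose(triple.i, cfg.nsct_spec, bank)
    pyr_b = nsct_decompose(ct_unit, cfg.nsct_spec, bank)
    if method == "nsct_fl":
        fused_pyr = _max_avg_fuse_pyramids(pyr_a, pyr_b)
        chosen: dict = {}
    else:  # nsct_pcnn
        fused_pyr, chosen = _fixed_param_fuse_pyramids(pyr_a, pyr_b, cfg)
    i_prime = nsct_reconstruct(fused_pyr, bank)
    return _finish(i_prime, triple, chosen, cfg, method, cfg.seed)
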