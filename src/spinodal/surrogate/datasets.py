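"""Dataset builders for the two surrogates.

*Pair data* (evolution surrogate): phase-field trajectories are run for a
ladder of noise means and neighboring saves are paired as (input, target);
the pairs are split 80/20 into train/validation by a seeded shuffle at the
pair level.

*Property data* (property surrogate): decomposition simulations with
randomly sampled patterned initializations; from each trajectory, binary
structures are extracted at a fixed ladder of increasingly spaced saves
(coarsening slows down, so early saves are sampled densely) and labeled by
FFT homogenization.  The split is 7/9 train, 1/9 validation, 1/9 test,
applied at the *simulation* level so near-duplicate structures from one
trajectory never straddle a split boundary.

Both builders expose exact counting identities (``*_counts``) so dataset
sizes can be audited without materializing anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np

from ..grids import GridSpec, PhaseField, ValidationError
from ..cahn_hilliard import CHParams, Trajectory, simulate
from ..fields import UniformInitSpec, init_uniform
from ..morphology import threshold_extract

__all__ = [
    "PairDataset",
    "PropertyDataset",
    "DEFAULT_MU_LADDER",
    "DEFAULT_EXTRACTION_STEPS",
    "pair_counts",
    "property_counts",
    "build_pair_dataset",
    "build_property_dataset",
]

#: equi-spaced noise means used for the evolution training simulations
DEFAULT_MU_LADDER = tuple(np.round(np.arange(-0.7, 0.7001, 0.1), 1))

#: increasingly spaced save indices at which structures are extracted for
#: the property dataset (coarsening slows down at late times)
DEFAULT_EXTRACTION_STEPS = (9, 11, 14, 18, 23, 29, 36, 44, 53, 63, 74, 86)


@dataclass
class PairDataset:
    """(input, target) save pairs with a seeded 80/20 train/val split."""

    x: np.ndarray          # (N, 1, X, Y, Z)
    y: np.ndarray          # (N, 1, X, Y, Z)
    train_idx: np.ndarray
    val_idx: np.ndarray
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.x) != len(self.y):
            raise ValidationError("inputs and targets must pair one-to-one")
        if len(self.train_idx) + len(self.val_idx) != len(self.x):
            raise ValidationError("split must partition the dataset")

    @property
    def splits(self) -> tuple[int, int]:
        return len(self.train_idx), len(self.val_idx)


@dataclass
class PropertyDataset:
    """(binary structure, 9 stiffness constants) with a 3-way split."""

    structures: np.ndarray  # (N, 1, X, Y, Z) binary
    labels: np.ndarray      # (N, 9) GPa
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    extraction_steps: tuple
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        steps = tuple(self.extraction_steps)
        if any(b <= a for a, b in zip(steps, steps[1:])):
            raise ValidationError("extraction steps must be strictly increasing")
        n = len(self.structures)
        if len(self.train_idx) + len(self.val_idx) + len(self.test_idx) != n:
            raise ValidationError("split must partition the dataset")

    @property
    def splits(self) -> tuple[int, int, int]:
        return len(self.train_idx), len(self.val_idx), len(self.test_idx)


def pair_counts(n_sims: int, saves_per_sim: int = 100) -> dict[str, int]:
    """Exact pair-dataset counting: one pair per neighboring-save step.

    A trajectory with ``saves_per_sim`` saves after the initial condition
    yields ``saves_per_sim`` pairs (save k -> save k+1 for k = 0..n-1).
    Validation takes every fifth pair (total // 5), training the remainder.
    """
    total = n_sims * saves_per_sim
    val = total // 5
    return {"total": total, "train": total - val, "validation": val}


def property_counts(n_sims: int, steps_per_sim: int = len(DEFAULT_EXTRACTION_STEPS)
                    ) -> dict[str, int]:
    """Exact property-dataset counting with the 7/9 : 1/9 : 1/9 split.

    Validation and test each take ``total // 9`` entries (simulation-level
    rounding is handled by the builder); training gets the remainder.
    """
    total = n_sims * steps_per_sim
    val = total // 9
    test = total // 9
    return {"total": total, "train": total - val - test,
            "validation": val, "test": test}


def build_pair_dataset(
    n_sims: int,
    mus: Optional[Sequence[float]] = None,
    params: Optional[CHParams] = None,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    save_stride: int = 1,
) -> PairDataset:
    """Run one simulation per noise mean and pair neighboring saves.

    ``mus`` defaults to the first ``n_sims`` entries of the equi-spaced
    ladder -0.7, -0.6, ..., 0.7 (all 15 when ``n_sims`` is 15).
    ``save_stride`` subsamples the saves (stride 1 pairs every neighboring
    save) for reduced-scale runs.  Fully deterministic for a fixed seed.
    """
    if mus is None:
        if n_sims == len(DEFAULT_MU_LADDER):
            mus = DEFAULT_MU_LADDER
        else:
            mus = tuple(np.round(np.linspace(-0.7, 0.7, n_sims), 4))
    if len(mus) != n_sims:
        raise ValidationError(f"need {n_sims} mu values, got {len(mus)}")
    params = params or CHParams()
    grid = params.make_grid(grid_shape)
    xs, ys = [], []
    rng = np.random.Generator(np.random.Philox(int(seed)))
    sim_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    for mu, sim_seed in zip(mus, sim_seeds):
        spec = UniformInitSpec(mu=float(mu), seed=int(sim_seed))
        try:
            traj = simulate(init_uniform(grid, spec), params)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed for mu={mu}, seed={sim_seed}: {exc}"
            ) from exc
        fields = [f.values for f in traj.saves[::save_stride]]
        for a, b in zip(fields[:-1], fields[1:]):
            xs.append(a[None])
            ys.append(b[None])
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys).astype(np.float32)
    n = len(x)
    counts = pair_counts(n_sims, (len(fields) - 1))
    order = np.random.Generator(np.random.Philox(int(seed) + 1)).permutation(n)
    val = order[:counts["validation"]]
    train = order[counts["validation"]:]
    return PairDataset(
        x=x, y=y, train_idx=np.sort(train), val_idx=np.sort(val),
        provenance={"mus": list(map(float, mus)), "seed": int(seed),
                    "sim_seeds": sim_seeds.tolist(),
                    "grid_shape": list(grid_shape),
                    "save_stride": save_stride},
    )


def build_property_dataset(
    n_sims: int,
    sampler,
    extraction_steps: Sequence[int] = DEFAULT_EXTRACTION_STEPS,
    material=None,
    generator: Optional[Callable[[PhaseField, int], Trajectory]] = None,
    params: Optional[CHParams] = None,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    seed: int = 0,
    dry_run: bool = False,
    homogenize_kwargs: Optional[dict] = None,
):
    """Patterned-initialization simulations labeled by FFT homogenization.

    ``sampler`` draws patterned initialization specs (see
    ``spinodal.design.ScreeningSampler``); ``generator`` maps an initial
    field and a number of steps to a trajectory (defaults to the physics
    solver; pass a surrogate rollout closure to use the learned model).
    Structures are extracted at ``extraction_steps``, thresholded at 0 and
    labeled with the nine orthotropic constants.  Entries whose
    homogenization fails to converge are skipped and logged.

    With ``dry_run=True`` no simulation runs; the exact counting identities
    are returned instead.
    """
    steps = tuple(int(s) for s in extraction_steps)
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise ValidationError("extraction steps must be strictly increasing")
    if dry_run:
        return property_counts(n_sims, len(steps))

    from ..mechanics import SolidElasticity, fft_homogenize, ConvergenceError

    material = material or SolidElasticity()
    params = params or CHParams(n_saves=max(steps))
    if params.n_saves < max(steps):
        raise ValidationError(
            f"params.n_saves={params.n_saves} < max extraction step {max(steps)}")
    grid = params.make_grid(grid_shape)
    if generator is None:
        generator = lambda init, n: simulate(
            init, CHParams(**{**params.__dict__, "n_saves": n}))

    structures, labels, skipped = [], [], []
    sim_of_entry = []
    for k in range(n_sims):
        spec = sampler.draw(k)
        init = spec.realize(grid)
        traj = generator(init, max(steps))
        for s in steps:
            st = threshold_extract(traj[s])
            if st.degenerate:
                skipped.append((k, s, "degenerate"))
                continue
            try:
                tensor = fft_homogenize(st, material,
                                        **(homogenize_kwargs or {}))
            except ConvergenceError as exc:
                skipped.append((k, s, str(exc)))
                continue
            structures.append(st.solid[None].astype(np.float32))
            labels.append(tensor.orthotropic_components)
            sim_of_entry.append(k)

    structures = np.stack(structures)
    labels = np.stack(labels)
    # simulation-level split: shuffle simulations, then allot entries
    order = np.random.Generator(np.random.Philox(int(seed) + 2)).permutation(n_sims)
    counts = property_counts(n_sims, len(steps))
    sim_of_entry = np.asarray(sim_of_entry)
    rank = np.empty(n_sims, dtype=int)
    rank[order] = np.arange(n_sims)
    entry_rank = rank[sim_of_entry]
    # simulations are allotted to splits in shuffled order until the split
    # quota (in entries) is covered; training gets the remainder
    sorted_entries = np.argsort(entry_rank, kind="stable")
    n_val = counts["validation"]
    n_test = counts["test"]
    val_idx = sorted_entries[:n_val]
    test_idx = sorted_entries[n_val:n_val + n_test]
    train_idx = sorted_entries[n_val + n_test:]
    return PropertyDataset(
        structures=structures, labels=labels,
        train_idx=np.sort(train_idx), val_idx=np.sort(val_idx),
        test_idx=np.sort(test_idx),
        extraction_steps=steps,
        provenance={"n_sims": n_sims, "seed": int(seed),
                    "skipped": skipped, "grid_shape": list(grid_shape)},
    )
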