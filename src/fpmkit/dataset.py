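"""Synthetic training-set construction.

Ground-truth complex amplitudes are made by randomly pairing grayscale
source images: one image supplies the amplitude, another (scaled to a
configurable phase range) supplies the phase.  Each truth field is pushed
through the forward model, noise is added to the low-resolution
intensities, the stack is fused into the dual-channel network input, and
aligned random crops of input and truth become the training examples.
A seeded shuffle splits them into train and test sets.

At the reference scale, 400 sources × multiplicity 4 give 1,600 truth
fields; 16 crops each give 25,600 examples; a 90/10 split gives
23,040 train / 2,560 test.

Because the crop plan, pairing and split are pure bookkeeping, the builder
separates the *manifest* (always computed at full scale, exact counts,
reproducible byte-for-byte from the seed) from *materialisation* (running
the forward model and synthesis for a chosen number of truth fields) — so
count algebra can be verified in seconds while pixel data is produced only
where needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, FormatError, InputError
from .forward import add_gaussian_noise, simulate_capture
from .optics import ComplexField, LEDGrid, OpticalConfig, make_ctf
from .synthesis import synthesize_input

__all__ = [
    "DatasetSpec",
    "DatasetManifest",
    "generate_synthetic_sources",
    "plan_truth_pairs",
    "build_truth_pairs",
    "build_dataset",
    "load_finetune_stub",
]


@dataclass(frozen=True)
class DatasetSpec:
    """Layout of one synthetic dataset build.

    Defaults reproduce the reference scale: 400 sources, 4 truth pairs per
    source, 16 crops per pair, 192-pixel crops, 90/10 split, noise σ 3e-4
    (on peak-normalised intensities), phase range [−π/2, π/2].
    """

    n_sources: int = 400
    pairing_multiplicity: int = 4
    crops_per_pair: int = 16
    crop_side: int = 192
    source_side: int = 256
    train_fraction: float = 0.9
    noise_sigma: float = 3e-4
    phase_range: tuple = (-np.pi / 2, np.pi / 2)
    seed: int = 0

    def __post_init__(self):
        problems = []
        if not (0 < self.train_fraction < 1):
            problems.append(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        for name in ("n_sources", "pairing_multiplicity", "crops_per_pair", "crop_side"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.crop_side > self.source_side:
            problems.append(
                f"crop_side {self.crop_side} exceeds source_side {self.source_side}"
            )
        if self.noise_sigma < 0:
            problems.append(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if problems:
            raise ConfigError("; ".join(problems))

    @property
    def n_pairs(self) -> int:
        return self.n_sources * self.pairing_multiplicity

    @property
    def n_total(self) -> int:
        return self.n_pairs * self.crops_per_pair

    @property
    def n_train(self) -> int:
        return int(round(self.train_fraction * self.n_total))

    @property
    def n_test(self) -> int:
        return self.n_total - self.n_train


@dataclass
class DatasetManifest:
    """Per-example provenance records plus global counts; rebuilding with
    the same spec and seed yields a byte-identical manifest."""

    spec: dict
    records: list = field(default_factory=list)
    n_total: int = 0
    n_train: int = 0
    n_test: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "spec": self.spec,
                "n_total": self.n_total,
                "n_train": self.n_train,
                "n_test": self.n_test,
                "records": self.records,
            },
            indent=None,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "DatasetManifest":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            spec=d["spec"],
            records=d["records"],
            n_total=d["n_total"],
            n_train=d["n_train"],
            n_test=d["n_test"],
        )


def generate_synthetic_sources(n: int, side: int = 256, seed: int = 0) -> np.ndarray:
    """Procedural grayscale images with tissue-like multi-scale texture.

    Each image combines low-pass-filtered noise at three spatial scales
    with soft-thresholded blob boundaries (mimicking cell/tissue edges),
    stretched to [0, 1].  Deterministic per seed; values in [0, 1] with a
    per-image mean kept away from the extremes.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    out = np.empty((n, side, side), dtype=float)
    for i in range(n):
        coarse = gaussian_filter(rng.normal(size=(side, side)), side / 16)
        mid = gaussian_filter(rng.normal(size=(side, side)), side / 48)
        fine = gaussian_filter(rng.normal(size=(side, side)), side / 128)
        blobs = gaussian_filter(rng.normal(size=(side, side)), side / 24)
        edges = np.tanh(8.0 * blobs / (np.std(blobs) + 1e-12))
        img = 2.0 * coarse + 1.0 * mid + 0.5 * fine + 0.8 * edges * np.std(mid)
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo if hi > lo else 1.0)
        # keep full contrast but re-centre extreme means towards 0.5
        m = img.mean()
        if m < 0.3 or m > 0.7:
            img = 0.5 + (img - m) * min(1.0, 0.45 / max(m, 1 - m))
            img = np.clip(img, 0.0, 1.0)
        out[i] = img
    return out


def plan_truth_pairs(n_sources: int, multiplicity: int, seed: int) -> list:
    """The (amplitude_index, phase_index) pairing, without touching pixels.

    The phase source is drawn uniformly over all images (with replacement
    across amplitude sources, without replacement within one amplitude's
    picks, so no (amplitude, phase) tuple repeats).
    """
    if multiplicity < 1:
        raise InputError(f"multiplicity must be >= 1, got {multiplicity}")
    if multiplicity > n_sources:
        raise InputError(
            f"multiplicity {multiplicity} exceeds the {n_sources} available phase sources"
        )
    rng = np.random.default_rng(seed)
    pairing: list[tuple[int, int]] = []
    for a_idx in range(n_sources):
        for p_idx in rng.choice(n_sources, size=multiplicity, replace=False):
            pairing.append((int(a_idx), int(p_idx)))
    return pairing


def _pair_field(
    images: np.ndarray, a_idx: int, p_idx: int, phase_range: tuple, pixel_um: float
) -> ComplexField:
    lo, hi = phase_range
    phase = lo + (hi - lo) * images[p_idx]
    return ComplexField(values=images[a_idx] * np.exp(1j * phase), pixel_um=pixel_um)


def build_truth_pairs(
    images: np.ndarray,
    multiplicity: int = 4,
    seed: int = 0,
    phase_range: tuple = (-np.pi / 2, np.pi / 2),
    pixel_um: float = 0.275,
) -> tuple[list, list]:
    """Pair every amplitude image with ``multiplicity`` distinct phase images.

    The phase map is the phase-source image rescaled linearly into
    ``phase_range``; the complex amplitude is ``a · exp(jφ)``.  Returns
    (fields, pairing) where pairing lists (amplitude_index, phase_index)
    tuples in build order; the pairing is exactly ``plan_truth_pairs``'s.
    """
    images = np.asarray(images, dtype=float)
    pairing = plan_truth_pairs(images.shape[0], multiplicity, seed)
    fields = [
        _pair_field(images, a, p, phase_range, pixel_um) for a, p in pairing
    ]
    return fields, pairing


def _plan_manifest(spec: DatasetSpec, pairing: list) -> DatasetManifest:
    """Crop plan and split, fully determined by the spec's seed."""
    rng = np.random.default_rng(spec.seed + 1)
    max_off = spec.source_side - spec.crop_side
    records = []
    gid = 0
    for pair_idx, (a_idx, p_idx) in enumerate(pairing):
        for c in range(spec.crops_per_pair):
            oy = int(rng.integers(0, max_off + 1))
            ox = int(rng.integers(0, max_off + 1))
            records.append(
                {
                    "group": gid,
                    "pair": pair_idx,
                    "amplitude_source": a_idx,
                    "phase_source": p_idx,
                    "crop_offset": [oy, ox],
                    "noise_seed": int((spec.seed * 100003 + pair_idx) % (2**31 - 1)),
                    "split": "train",  # provisional, assigned below
                    "shard": None,
                    "shard_index": None,
                }
            )
            gid += 1
    split_rng = np.random.default_rng(spec.seed + 2)
    perm = split_rng.permutation(len(records))
    train_ids = set(perm[: spec.n_train].tolist())
    for r in records:
        r["split"] = "train" if r["group"] in train_ids else "test"
    return DatasetManifest(
        spec=_spec_dict(spec),
        records=records,
        n_total=len(records),
        n_train=spec.n_train,
        n_test=spec.n_test,
    )


def _spec_dict(spec: DatasetSpec) -> dict:
    d = asdict(spec)
    d["phase_range"] = list(d["phase_range"])
    return d


def build_dataset(
    spec: DatasetSpec,
    optics: OpticalConfig,
    grid: LEDGrid,
    out_dir=None,
    *,
    materialize: int | bool = False,
    sources: np.ndarray | None = None,
) -> tuple[DatasetManifest, dict]:
    """Plan (and optionally materialise) a full dataset.

    The manifest — pairing, crop offsets, noise seeds, split labels and all
    counts — is always produced at full scale.  ``materialize`` selects how
    many truth pairs to actually push through simulate → noise → synthesis
    (``True`` for all, an int for the first k, ``False`` for none); the
    corresponding example arrays are returned in memory and, if ``out_dir``
    is given, written as an HDF5 shard with datasets ``input`` and
    ``truth`` of shape [N, 2, S, S], next to ``manifest.json``.
    """
    if spec.source_side % optics.upsample_factor != 0:
        raise ConfigError(
            f"source_side {spec.source_side} not divisible by upsample_factor "
            f"{optics.upsample_factor}"
        )
    if sources is not None and (
        sources.shape[0] != spec.n_sources or sources.shape[1] != spec.source_side
    ):
        raise InputError(
            f"sources shape {sources.shape} does not match spec "
            f"({spec.n_sources}, {spec.source_side}, {spec.source_side})"
        )
    pairing = plan_truth_pairs(spec.n_sources, spec.pairing_multiplicity, spec.seed)
    manifest = _plan_manifest(spec, pairing)

    n_pairs_todo = 0
    if materialize is True:
        n_pairs_todo = len(pairing)
    elif materialize:
        n_pairs_todo = min(int(materialize), len(pairing))

    inputs, truths, mat_groups = [], [], []
    if n_pairs_todo > 0:
        # pixels are only touched when materialising
        if sources is None:
            sources = generate_synthetic_sources(spec.n_sources, spec.source_side, spec.seed)
        ctf = make_ctf(optics, spec.source_side // optics.upsample_factor)
        by_pair: dict[int, list] = {}
        for r in manifest.records:
            by_pair.setdefault(r["pair"], []).append(r)
        for pair_idx in range(n_pairs_todo):
            a_idx, p_idx = pairing[pair_idx]
            truth_field = _pair_field(
                sources, a_idx, p_idx, spec.phase_range, optics.object_pixel_um
            )
            stack = simulate_capture(truth_field, optics, grid, ctf=ctf)
            recs = by_pair[pair_idx]
            if spec.noise_sigma > 0:
                stack = add_gaussian_noise(stack, spec.noise_sigma, recs[0]["noise_seed"])
            dual = synthesize_input(stack, ctf, optics)
            inp_full = dual.stacked()
            tru_full = np.stack(
                [np.abs(truth_field.values) ** 2, np.angle(truth_field.values)], axis=0
            )
            for r in recs:
                oy, ox = r["crop_offset"]
                s = spec.crop_side
                inputs.append(inp_full[:, oy : oy + s, ox : ox + s])
                truths.append(tru_full[:, oy : oy + s, ox : ox + s])
                r["shard"] = "shard_000.h5"
                r["shard_index"] = len(inputs) - 1
                mat_groups.append(r["group"])

    data = {
        "input": np.asarray(inputs) if inputs else np.empty((0, 2, spec.crop_side, spec.crop_side)),
        "truth": np.asarray(truths) if truths else np.empty((0, 2, spec.crop_side, spec.crop_side)),
        "groups": np.asarray(mat_groups, dtype=int),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.to_json(out / "manifest.json")
        if n_pairs_todo > 0:
            import h5py

            with h5py.File(out / "shard_000.h5", "w") as h5:
                h5.create_dataset("input", data=data["input"].astype(np.float32))
                h5.create_dataset("truth", data=data["truth"].astype(np.float32))
                h5.create_dataset("groups", data=data["groups"])
                h5.attrs["seed"] = spec.seed
    return manifest, data


def load_finetune_stub(path) -> dict:
    """Load externally supplied acquisition pairs in the dataset layout.

    Reads every ``*.h5`` shard under ``path`` (datasets ``input`` and
    ``truth``, [N, 2, S, S]) plus ``manifest.json`` if present; performs no
    generation.  An empty directory yields an empty dataset.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"path does not exist: {p}")
    import h5py

    inputs, truths = [], []
    for shard in sorted(p.glob("*.h5")):
        with h5py.File(shard, "r") as h5:
            if "input" not in h5 or "truth" not in h5:
                raise FormatError(f"{shard} lacks the required 'input'/'truth' datasets")
            inputs.append(h5["input"][...])
            truths.append(h5["truth"][...])
    manifest = None
    mpath = p / "manifest.json"
    if mpath.exists():
        manifest = DatasetManifest.from_json(mpath)
    if inputs:
        data_in = np.concatenate(inputs, axis=0)
        data_tr = np.concatenate(truths, axis=0)
    else:
        data_in = np.empty((0, 2, 0, 0))
        data_tr = np.empty((0, 2, 0, 0))
    return {"input": data_in, "truth": data_tr, "manifest": manifest}


def mix_finetune(sim_data: dict, fine_data: dict, ratio: float, seed: int) -> dict:
    """Seeded interleaving of a fine-tuning set into a simulated set.

    ``ratio`` is the fraction of fine-tune examples to draw (of those
    available); the combined examples are shuffled deterministically.
    """
    if not (0 <= ratio <= 1):
        raise InputError(f"ratio must be in [0, 1], got {ratio}")
    rng = np.random.default_rng(seed)
    n_fine = int(round(ratio * fine_data["input"].shape[0]))
    pick = rng.choice(fine_data["input"].shape[0], size=n_fine, replace=False) if n_fine else []
    inp = np.concatenate([sim_data["input"], fine_data["input"][pick]], axis=0)
    tru = np.concatenate([sim_data["truth"], fine_data["truth"][pick]], axis=0)
    perm = rng.permutation(inp.shape[0])
    return {"input": inp[perm], "truth": tru[perm]}
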