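import numpy as np
import pytest

from pdflow import (
    DatasetHandle,
    PoseSequence,
    default_benchmark_spec,
    generate_dataset,
    normalize_dataset,
)


def write_skeleton_file(path, frames):
    """Write an NTU-dialect .skeleton file.

    `frames` is a list of frames; each frame is a list of bodies; each body
    is a (body_id, joints) pair with joints a (J, 3) array.  Joint lines
    carry the NTU 12-column layout (x y z + 8 auxiliary + tracking state).
    """
    lines = [str(len(frames))]
    for bodies in frames:
        lines.append(str(len(bodies)))
        for body_id, joints in bodies:
            lines.append(f"{body_id} 0 0 0 0 0 0 0 0 2")
            joints = np.asarray(joints, dtype=float)
            lines.append(str(len(joints)))
            for x, y, z in joints:
                lines.append(f"{x} {y} {z} 0 0 0 0 1 0 0 0 2")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def skeleton_writer():
    return write_skeleton_file


def small_sequence(T=6, J=5, seed=0, label=None):
    rng = np.random.default_rng(seed)
    return PoseSequence(coords=rng.normal(size=(T, J, 3)), label=label, seq_id=f"s{seed}")


@pytest.fixture
def random_sequence():
    return small_sequence()


@pytest.fixture
def random_dataset():
    seqs = [small_sequence(T=5 + i, seed=i, label=i % 2) for i in range(4)]
    return DatasetHandle(
        sequences=seqs, labels=[s.label for s in seqs], split_tag="train",
        meta={"note": "fixture"},
    )


@pytest.fixture(scope="session")
def benchmark_data():
    """Small normalized synthetic benchmark shared by training-level tests."""
    spec = default_benchmark_spec(per_class_train=2, per_class_test=2)
    train, test = generate_dataset(spec)
    return normalize_dataset(train), normalize_dataset(test)
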