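import numpy as np
import pytest

from hrea import generate_dataset
from hrea.preprocessing import make_window, split_dataset


@pytest.fixture(scope="session")
def dataset150():
    """150 synthetic recordings: 5 actions x 3 scores x 10, fixed seed."""
    return generate_dataset(10, seed=2024)


@pytest.fixture(scope="session")
def split150(dataset150):
    labels = [r.score_label for r in dataset150]
    return split_dataset(dataset150, labels, (0.6, 0.2, 0.2), seed=5)


@pytest.fixture()
def fake_ucihar(tmp_path):
    """Tiny synthetic directory in the UCI-HAR text layout (12 windows/split)."""
    rng = np.random.default_rng(99)
    for split, n in (("train", 12), ("test", 12)):
        sig_dir = tmp_path / split / "Inertial Signals"
        sig_dir.mkdir(parents=True)
        labels = np.tile(np.arange(1, 7), n // 6)
        np.savetxt(tmp_path / split / f"y_{split}.txt", labels, fmt="%d")
        for name in ("body_acc_x", "body_acc_y", "body_acc_z",
                     "body_gyro_x", "body_gyro_y", "body_gyro_z"):
            np.savetxt(sig_dir / f"{name}_{split}.txt",
                       rng.normal(0, 0.3, (n, 128)), fmt="%.6e")
    return tmp_path


@pytest.fixture(scope="session")
def windows_for():
    def _make(recordings, channel, length=128):
        return [make_window(r, channel, None, length) for r in recordings]
    return _make
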