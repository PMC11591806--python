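import numpy as np
import pytest

from bcdpipe import LabeledTable


@pytest.fixture
def separable_table() -> LabeledTable:
    """Two tight, well-separated 2-D clusters: 8 benign + 8 malignant."""
    rng = np.random.default_rng(12345)
    benign = rng.normal([2.0, 2.0], 0.2, (8, 2))
    malignant = rng.normal([8.0, 8.0], 0.2, (8, 2))
    values = np.vstack([benign, malignant])
    labels = np.array(["benign"] * 8 + ["malignant"] * 8, dtype=object)
    return LabeledTable(values, labels, ["f1", "f2"])


@pytest.fixture
def wbcd_file(tmp_path):
    """Factory writing a WBCD-dialect file from raw lines."""

    def make(lines, name="toy.data"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return make
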