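import numpy as np
import pytest

from xmricc import ExpenditureMatrix, month_labels


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_matrix(rng):
    """5 cases x 36 months of positive monthly amounts (3 whole years)."""
    values = 100.0 + 5.0 * rng.standard_normal((5, 36))
    return ExpenditureMatrix(
        case_ids=[f"h{i}" for i in range(5)],
        month_labels=month_labels("1999-01", 36),
        values=values,
    )


@pytest.fixture
def wide_csv(tmp_path, rng):
    """Wide CSV with 4 rows, one of which has a missing cell."""
    labels = month_labels("1999-01", 14)
    lines = ["id," + ",".join(labels)]
    for i in range(4):
        cells = [f"{v:.2f}" for v in 100 + rng.standard_normal(14)]
        if i == 2:
            cells[5] = ""  # incomplete row -> must be dropped
        lines.append(f"h{i}," + ",".join(cells))
    path = tmp_path / "wide.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
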