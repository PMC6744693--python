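import numpy as np
import pytest

from normgene.expr_io import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, all positive."""
    return ExpressionMatrix(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2", "s3", "s4"),
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [10.0, 10.5, 9.5, 10.0],
                [0.0, 0.0, 5.0, 6.0],
            ]
        ),
    )


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
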