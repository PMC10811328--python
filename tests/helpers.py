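import numpy as np
import pandas as pd

from teqtl.datatypes import PhenotypeTable


def make_phenotype_table(values: np.ndarray, feature_class="gene", stage="counts",
                         chrom="chr1", spacing=100_000) -> PhenotypeTable:
    """Wrap a samples x features array into a PhenotypeTable."""
    values = np.asarray(values)
    n_samples, n_features = values.shape
    ids = [f"f{j:04d}" for j in range(n_features)]
    feats = pd.DataFrame(
        {
            "chrom": chrom,
            "start": spacing * (np.arange(n_features) + 1),
            "end": spacing * (np.arange(n_features) + 1) + 1000,
            "strand": "+",
            "feature_class": feature_class,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    vals = pd.DataFrame(values, index=pd.Index([f"s{i:04d}" for i in range(n_samples)],
                                              name="sample_id"), columns=ids)
    return PhenotypeTable(feats, vals, stage=stage)
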