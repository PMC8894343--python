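"""Atlas-label registry for the 139 regional grey-matter volumes.

The registry mirrors the Harvard-Oxford cortical (48 labels x 2 hemispheres)
and subcortical naming plus cerebellar lobule parcels, giving the 139 region
ids used as column names in imaging tables throughout the package.
"""

from importlib import resources

import pandas as pd

_REGISTRY_CACHE = None


def load_atlas_registry() -> pd.DataFrame:
    """Return the bundled region registry.

    Columns: ``region_id`` (table column name), ``hemisphere`` (L/R/M) and
    ``name`` (human-readable label). 139 rows.
    """
    global _REGISTRY_CACHE
    if _REGISTRY_CACHE is None:
        ref = resources.files("sleepcog.data").joinpath("atlas_regions.tsv")
        with ref.open("r") as fh:
            _REGISTRY_CACHE = pd.read_csv(fh, sep="\t", dtype=str)
    return _REGISTRY_CACHE.copy()


def region_ids(n_regions: int | None = None) -> list[str]:
    """Region-id column names, truncated or cycled to ``n_regions``.

    For the default 139 the registry ids are returned as-is; simulations with
    a different region count get synthetic ids beyond the registry.
    """
    ids = load_atlas_registry()["region_id"].tolist()
    if n_regions is None or n_regions == len(ids):
        return ids
    if n_regions <= len(ids):
        return ids[:n_regions]
    extra = [f"r{i:03d}_x_synthetic" for i in range(len(ids), n_regions)]
    return ids + extra
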