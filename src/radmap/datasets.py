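"""Small published reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def sockeye_shared_spans() -> pd.DataFrame:
    """Published per-linkage-group shared-marker spans (cM) for the sockeye
    salmon HX13-WL full-sib family: the distance between the most proximal
    and most distal markers shared by the female and male maps, per group.

    Columns: ``group``, ``female_cM``, ``male_cM``.
    """
    ref = resources.files("radmap") / "data" / "sockeye_shared_spans.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"group": str})
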