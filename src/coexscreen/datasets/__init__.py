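"""Bundled reference datasets.

Two published reference tables from the CD274 psoriasis co-expression
study (GEO accession GSE114286) that the screen was designed around:

* ``cd274_partner_correlations`` — genes significantly correlated with
  CD274 in each group's network (normal controls NN, n=9; psoriatic
  patients PP, n=18) with the published Pearson r, p-value, FDR and style.
* ``cd274_screen_topology`` — the published top-20 differential-hubness
  records (per-group degree and k-core with their case-minus-control
  differences); CD274 is the anchor of the published screen.
"""

from importlib import resources

import pandas as pd

from coexscreen.topology import TopologyRecord

#: group sample sizes of the reference study
N_SAMPLES = {"NN": 9, "PP": 18}

#: anchor gene of the reference screen
REFERENCE_ANCHOR = "CD274"


def _path(name: str):
    return resources.files(__package__) / name


def load_cd274_partner_correlations() -> pd.DataFrame:
    """Published CD274 correlation partners per group.

    Columns: group (NN/PP), gene, pearson_r, p_value, fdr, style.
    """
    with resources.as_file(_path("cd274_partner_correlations.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"group": str, "gene": str, "style": str})


def load_cd274_screen_topology() -> list[TopologyRecord]:
    """Published top-20 differential-hubness records as TopologyRecord fixtures.

    The bundled dif columns are redundant with the per-group values and are
    dropped on load; TopologyRecord recomputes them.
    """
    with resources.as_file(_path("cd274_screen_topology.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": str})
    return [
        TopologyRecord(
            gene_id=row.gene_id,
            degree_case=int(row.degree_case),
            degree_control=int(row.degree_control),
            kcore_case=int(row.kcore_case),
            kcore_control=int(row.kcore_control),
        )
        for row in df.itertuples()
    ]


def load_cd274_screen_topology_frame() -> pd.DataFrame:
    """Raw published topology table, including the published dif columns."""
    with resources.as_file(_path("cd274_screen_topology.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"gene_id": str})
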