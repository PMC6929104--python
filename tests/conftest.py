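"""Shared fixtures: the frozen published consistency table and record helpers."""

import pytest

from mirconcord import DERecord, GeneKey, parse_mirna_name

# Published per-dataset values for the 20 microRNAs reported as consistent in
# at least three of four pluripotency datasets: row label (hairpin, mature),
# two human comparisons (log2FC, padj each), three mouse study log2FCs
# (0.00 = not observed), and the printed consistent-dataset count.
PUBLISHED_CONSISTENCY_ROWS = [
    ("hsa-mir-143", "hsa-miR-143-3p", 4.10, 7.50, 2.932e-3, 1.163e-7, 2.16, 1.70, 0.79, 4),
    ("hsa-mir-200c", "hsa-miR-200c-3p", -6.60, -8.97, 8.956e-96, 5.294e-93, 6.44, -1.03, -0.88, 3),
    ("hsa-mir-205", "hsa-miR-205-5p", 3.23, 9.28, 4.715e-12, 1.392e-88, 2.23, 0.93, -1.28, 3),
    ("hsa-mir-302c", "hsa-miR-302c-3p", -1.68, -6.40, 5.552e-13, 1.086e-66, -5.47, -1.12, 2.63, 3),
    ("hsa-mir-20b", "hsa-miR-20b-5p", -1.93, -5.37, 1.923e-16, 2.778e-51, 0.00, -1.60, -0.75, 3),
    ("hsa-mir-335", "hsa-miR-335-5p", -1.76, -5.07, 1.075e-13, 6.196e-47, 0.00, -1.00, -0.74, 3),
    ("hsa-mir-302a", "hsa-miR-302a-3p", -1.50, -4.46, 1.090e-10, 8.146e-39, -5.15, -2.08, 1.67, 3),
    ("hsa-mir-412", "hsa-miR-412-5p", 7.17, 15.02, 3.547e-64, 1.038e-28, -2.60, 0.92, 3.34, 3),
    ("hsa-mir-433", "hsa-miR-433-3p", 5.38, 15.02, 6.536e-39, 7.545e-21, 0.00, 0.62, 4.29, 3),
    ("hsa-mir-495", "hsa-miR-495-3p", 4.68, 7.47, 2.492e-34, 1.098e-19, 0.00, 0.60, 4.27, 3),
    ("hsa-mir-582", "hsa-miR-582-3p", 2.72, 5.91, 7.063e-12, 4.664e-14, 1.40, 0.96, 0.48, 3),
    ("hsa-mir-196a-1", "hsa-miR-196a-5p", 8.96, 15.02, 1.038e-15, 1.389e-13, 0.00, 2.46, 0.78, 3),
    ("hsa-mir-196a-2", "hsa-miR-196a-5p", 8.69, 15.02, 2.845e-12, 2.660e-12, 0.00, 2.46, 0.78, 3),
    ("hsa-mir-200a", "hsa-miR-200a-5p", -3.37, -4.71, 1.511e-6, 5.775e-9, 0.00, -0.89, -1.59, 3),
    ("hsa-mir-1247", "hsa-miR-1247-3p", 3.40, 15.02, 1.677e-8, 4.527e-6, 2.85, 0.00, 2.17, 3),
    ("hsa-mir-708", "hsa-miR-708-3p", 1.13, 1.45, 5.997e-5, 3.027e-4, 1.87, 0.72, 0.08, 3),
    ("hsa-mir-199b", "hsa-miR-199b-3p", 3.34, 4.27, 4.641e-2, 6.808e-3, 2.54, 0.30, 1.01, 3),
    ("hsa-let-7f-2", "hsa-let-7f-5p", 4.79, 4.43, 1.363e-2, 8.710e-3, 0.00, 1.97, 0.78, 3),
    ("hsa-let-7f-1", "hsa-let-7f-5p", 4.72, 4.31, 1.455e-2, 9.959e-3, 0.00, 1.97, 0.78, 3),
    ("hsa-mir-182", "hsa-miR-182-3p", 3.19, 4.10, 7.430e-4, 2.571e-2, 0.00, 0.64, 0.88, 3),
]

MOUSE_STUDIES = ("Jouneau", "Gu", "Moradi")


@pytest.fixture
def published_consistency_rows():
    return PUBLISHED_CONSISTENCY_ROWS


def mir_record(name, log2fc, padj=1e-6, study="S1", species="human"):
    return DERecord(
        feature=parse_mirna_name(name), log2fc=log2fc, padj=padj,
        study=study, species=species,
    )


def gene_record(symbol, log2fc, padj=1e-6, study="S1", species="human"):
    return DERecord(
        feature=GeneKey(symbol, species), log2fc=log2fc, padj=padj,
        study=study, species=species,
    )
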