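"""Independently transcribed copy of the published 25-CpG clock table.

Retyped directly from the printed table (locus, site label, GRCh38
position, bold previous-model flag, regression coefficient) as a fixture
to cross-check the bundled model against; deliberately NOT imported from
the package.
"""

# (gene, label, chrom, position, in_previous_models, coefficient)
PUBLISHED_CLOCK_TABLE = [
    ("miR29B2C", "C1", "chr1", 207823681, True, -0.031),
    ("miR29B2C", "C2", "chr1", 207823705, False, -0.0242),
    ("FHL2", "C1", "chr2", 105399282, True, 0.0354),
    ("FHL2", "C2", "chr2", 105399288, True, 0.1146),
    ("FHL2", "C3", "chr2", 105399297, False, 0.0561),
    ("FHL2", "C4", "chr2", 105399300, False, 0.039),
    ("FHL2", "C5", "chr2", 105399327, False, -0.0837),
    ("FHL2", "C6", "chr2", 105399360, False, -0.6492),
    ("FHL2", "C7", "chr2", 105399363, False, -0.2134),
    ("FHL2", "C8", "chr2", 105399388, False, 0.057),
    ("TRIM59", "C1", "chr3", 160450179, False, 0.1184),
    ("TRIM59", "C2", "chr3", 160450184, False, 0.0528),
    ("TRIM59", "C3", "chr3", 160450189, True, 0.138),
    ("TRIM59", "C4", "chr3", 160450192, False, 0.0748),
    ("TRIM59", "C5", "chr3", 160450199, True, 0.0824),
    ("ELOVL2", "C1", "chr6", 11044628, True, 0.1533),
    ("ELOVL2", "C2", "chr6", 11044634, False, 0.2957),
    ("ELOVL2", "C3", "chr6", 11044640, False, 0.0894),
    ("ELOVL2", "C4", "chr6", 11044644, False, 0.0852),
    ("ELOVL2", "C5", "chr6", 11044647, False, 0.1189),
    ("ELOVL2", "C6", "chr6", 11044655, False, 0.0631),
    ("ELOVL2", "C7", "chr6", 11044661, True, 0.2512),
    ("ELOVL2", "C8", "chr6", 11044683, False, -0.0028),
    ("ELOVL2", "C9", "chr6", 11044702, False, -0.0712),
    ("KLF14", "C1", "chr7", 130734398, False, 0.2441),
]
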