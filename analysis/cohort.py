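"""The synthetic study cohort shared by the numbered analysis drivers.

Six phantoms spanning both planning groups and the three tumor-shape
families: large targets (> 15 cc, lattice group) and small targets
(3-15 cc, SCART group), with planning margins inside the 2-15 mm
clinical range."""

import sfrtplan as sp

COHORT = [
    ("S1_ellipsoid_67cc", sp.PhantomSpec(gtv_shape="ellipsoid", gtv_scale=67.0,
                                         ptv_margin=3.0, seed=101)),
    ("S2_strip_25cc", sp.PhantomSpec(gtv_shape="strip", gtv_scale=25.0,
                                     ptv_margin=3.0, seed=102)),
    ("S3_star_40cc", sp.PhantomSpec(gtv_shape="star", gtv_scale=40.0,
                                    ptv_margin=5.0, seed=103)),
    ("S4_ellipsoid_8cc", sp.PhantomSpec(gtv_shape="ellipsoid", gtv_scale=8.0,
                                        ptv_margin=5.0, seed=104)),
    ("S5_strip_12cc", sp.PhantomSpec(gtv_shape="strip", gtv_scale=12.0,
                                     ptv_margin=4.0, seed=105)),
    ("S6_star_10cc", sp.PhantomSpec(gtv_shape="star", gtv_scale=10.0,
                                    ptv_margin=4.0, seed=106)),
]

RESULTS_DIR = "results"
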