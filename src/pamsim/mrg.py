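"""Geometric and membrane parameter tables of the double-cable myelinated
axon model of McIntyre, Richardson & Grill (2002), J Neurophysiol 87:995-1006
(MRG model), as published with the model's reference implementation.

Each internode repeats 11 compartments: one node of Ranvier, two
myelin-attachment segments (MYSA), two paranode main segments (FLUT), and
six internodal segments (STIN).  The table keys are fiber (myelin outer)
diameters in micrometres; values are micrometres unless noted.

The published table bottoms out at 5.7 um.  Thin collaterals (e.g. the
1.8 um hyperdirect branches) are generated by scaling the 5.7 um row
proportionally with fiber diameter (node and MYSA lengths kept fixed, as
they are in the published table across all diameters); a linear fit of the
low-diameter published rows extrapolates the internodal spacing negative
below ~2.5 um and is therefore not used.
"""

from __future__ import annotations

__all__ = ["MRG_GEOMETRY_TABLE", "MRG_MEMBRANE", "geometry_row"]

# fiberD -> dict of published geometric parameters (um, except nl)
#   axonD: internodal axolemma diameter; nodeD: node/MYSA diameter;
#   paraD2: FLUT/STIN sheath-level axon diameter (equals axonD);
#   deltax: node-to-node internodal spacing; flut_len: FLUT length;
#   nl: myelin lamellae count.
MRG_GEOMETRY_TABLE = {
    5.7:  dict(axonD=3.4,  nodeD=1.9, deltax=500.0,  flut_len=35.0, nl=80),
    7.3:  dict(axonD=4.6,  nodeD=2.4, deltax=750.0,  flut_len=38.0, nl=100),
    8.7:  dict(axonD=5.8,  nodeD=2.8, deltax=1000.0, flut_len=40.0, nl=110),
    10.0: dict(axonD=6.9,  nodeD=3.3, deltax=1150.0, flut_len=46.0, nl=120),
    11.5: dict(axonD=8.1,  nodeD=3.7, deltax=1250.0, flut_len=50.0, nl=130),
    12.8: dict(axonD=8.8,  nodeD=4.2, deltax=1350.0, flut_len=54.0, nl=135),
    14.0: dict(axonD=9.2,  nodeD=4.7, deltax=1400.0, flut_len=56.0, nl=140),
    16.0: dict(axonD=10.9, nodeD=5.5, deltax=1500.0, flut_len=60.0, nl=150),
}

NODE_LENGTH_UM = 1.0
MYSA_LENGTH_UM = 3.0

# periaxonal space widths (um) under each compartment type
PERIAXONAL_SPACE_UM = dict(node=0.002, mysa=0.002, flut=0.004, stin=0.004)

# membrane/electrical constants of the published model (36 C)
MRG_MEMBRANE = dict(
    rhoa_ohm_cm=70.0,          # axoplasmic / periaxonal resistivity
    cm_uF_per_cm2=2.0,         # axolemma specific capacitance (all types)
    mycm_uF_per_cm2=0.1,       # myelin capacitance per lamella membrane
    mygm_S_per_cm2=0.001,      # myelin conductance per lamella membrane
    gnabar_S_per_cm2=3.0,      # nodal fast Na+
    gnapbar_S_per_cm2=0.01,    # nodal persistent Na+
    gkbar_S_per_cm2=0.08,      # nodal slow K+
    gl_S_per_cm2=0.007,        # nodal leak
    g_mysa_S_per_cm2=0.001,    # passive axolemma, MYSA
    g_flut_S_per_cm2=0.0001,   # passive axolemma, FLUT
    g_stin_S_per_cm2=0.0001,   # passive axolemma, STIN
    ena_mV=50.0,
    ek_mV=-90.0,
    el_mV=-90.0,
    e_pas_mV=-80.0,            # passive-compartment reversal (rest)
    vrest_mV=-80.0,
    celsius=36.0,
)


def geometry_row(fiber_diameter_um: float) -> dict:
    """Geometric parameters for a fiber diameter.

    Published diameters return the table row; diameters between published
    rows are linearly interpolated; diameters below 5.7 um scale the
    5.7 um row proportionally with diameter (lengths of node and MYSA
    fixed at the table-wide 1.0 and 3.0 um).
    """
    keys = sorted(MRG_GEOMETRY_TABLE)
    d = float(fiber_diameter_um)
    if d in MRG_GEOMETRY_TABLE:
        row = dict(MRG_GEOMETRY_TABLE[d])
    elif d < keys[0]:
        ratio = d / keys[0]
        base = MRG_GEOMETRY_TABLE[keys[0]]
        row = dict(
            axonD=base["axonD"] * ratio,
            nodeD=base["nodeD"] * ratio,
            deltax=base["deltax"] * ratio,
            flut_len=base["flut_len"] * ratio,
            nl=max(2, int(round(base["nl"] * ratio))),
        )
    elif d > keys[-1]:
        raise ValueError(f"fiber diameter {d} um above the published table")
    else:
        import bisect
        hi = bisect.bisect_left(keys, d)
        k0, k1 = keys[hi - 1], keys[hi]
        w = (d - k0) / (k1 - k0)
        r0, r1 = MRG_GEOMETRY_TABLE[k0], MRG_GEOMETRY_TABLE[k1]
        row = {k: (1 - w) * r0[k] + w * r1[k] for k in r0}
        row["nl"] = int(round(row["nl"]))
    row["fiberD"] = d
    row["node_len"] = NODE_LENGTH_UM
    row["mysa_len"] = MYSA_LENGTH_UM
    row["stin_len"] = (row["deltax"] - row["node_len"] - 2 * row["mysa_len"]
                       - 2 * row["flut_len"]) / 6.0
    if row["stin_len"] <= 0:
        raise ValueError(f"degenerate internode for diameter {d} um")
    return row
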