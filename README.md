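# icrsfem

Two-dimensional finite-element simulation of **intracorneal ring segment
(ICRS) implantation** with sagittal-curvature post-processing — a research
tool for comparing ring designs (constant versus variable thickness and
base width) by the local refractive change they induce, aimed at corneal
biomechanics researchers and ophthalmic device designers studying
keratoconus treatment.

## The model

The cornea is a three-layered band (epithelium, anterior stroma, posterior
stroma) between two circular arcs (anterior radius 7.8 mm, posterior
6.4 mm, central thickness 550 μm, or 450 μm for a thin keratoconus-like
variant), pinned at the limbus and loaded by an intraocular pressure of
15 mmHg on the posterior surface. The stroma is transversely isotropic —
stiff along the collagen lamellae, soft across them — with the compliance
(local circumferential *c* / radial *r* axes)

    eps_cc = sig_cc/E_c − (nu_rc/E_r) sig_rr − (nu_cc/E_c) sig_hh
    eps_rr = sig_rr/E_r − (nu_rc/E_r)(sig_cc + sig_hh)
    gam_rc = sig_rc/G_rc

(anterior stroma E_r = 500 kPa, E_c = 1 MPa, G_rc = 20 kPa; posterior
stroma 400/800/16 kPa; ν = 0.34), plus a layer-wise pre-strain (−1.5%
radial / +1.5% circumferential anterior, +1.0% posterior) that represents
the IOP-loaded reference state. Two 2D idealizations are solved with
8-node quadrilateral elements: **axisymmetric** (cornea as hemisphere,
360° ring — upper bound of the correction) and **plane strain** (cornea as
half-cylinder, unilateral segment — lower bound).

A ring with triangular cross-section (thickness 150–300 μm, base width
600–800 μm along a 160° arc) is implanted in silico: a stromal tunnel of
800 × 30 μm at 70% depth is carved, the tunnel boundary is displaced onto
the triangle of the cross-section at the chosen arc angle, bound rigid,
and released axially so the ring settles into equilibrium. Because the
imposed displacements are large on the scale of the corneal thickness, the
implantation is solved with an incremental Newton driver that tracks
stress and carries the membrane (initial-stress) stiffness. The refractive
outcome is read from the deformed anterior surface as **sagittal power**,
P(x) = (n − 1)·1000 / r_ax(x) dioptres with r_ax the distance along the
surface normal to the apex axis and n = 1.3375 the keratometric index, and
as the power change of the **best-fit sphere** over a 10 mm zone.

## Worked example

Simulate the asymmetric ring at its thick/wide end (160°: thickness
300 μm, base 800 μm) in the axisymmetric model:

```bash
icrsfem simulate --mode axisymmetric --angle 160
```

which prints

```
design asymmetric @ 160 deg, axisymmetric, cct 550 um
  central power change :    -2.02 D
  peripheral extreme   :   -41.79 D
  central 4 mm zone    :    -2.41 D
  best-fit sphere 10 mm:    -0.94 D
```

The peripheral extreme is the most negative change of sagittal power in
the 1–5 mm annulus: the ring lifts the surface locally and the power at
the crest collapses toward zero, a flattening of ~43 D relative to the
43.3 D pre-operative cornea. The central value is the change at the apex
(negative = central flattening), the 4 mm zone value its mean over the
central optical zone, and the best-fit-sphere change summarizes the whole
10 mm zone. The same library calls are available in Python:

```python
from icrsfem import RingDesign, make_context
from icrsfem.experiments import run_case

ctx = make_context(mode="axisymmetric")          # mesh + pre-op solve
res = run_case(ctx, RingDesign.asymmetric(), 160.0)
print(res.central_dD, res.peripheral_dD, res.zone4_dD, res.bfs10_dD)
```

`icrsfem study` sweeps all four designs × three arc stations × both
mechanical modes and writes a result table; `icrsfem curvature` post-
processes any exported surface polyline; `icrsfem validate` runs the
closed-form Lamé oracles. See `docs/methods.md` for the model's
assumptions, numerical choices and limitations.

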