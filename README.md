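# visemech

Mechanics and statistical-mechanical FRET modelling of DNA **molecular
vises** — hairpin nanostructures whose stem base-pairing applies a
near-constant ~9 pN compressive force to a short duplex "target strand",
probing DNA bending at curvatures far beyond thermal reach.  The package
is for biophysicists analysing vise-style FRET data (or designing such
constructs): it predicts the full FRET-versus-target-length curves, the
Euler buckling transition, the salt-induced melt-bubble kinking
transition, and the flexibility ranking of base-pairing mismatches, and
it quantifies raw three-channel gel intensities into FRET efficiencies.

## The model in brief

A vise is a hairpin with a loop of `L` = 30–50 nt, a 49-bp stem whose 39
loop-proximal base pairs are all A-T, and a target duplex of `h` bp formed
at the loop apex.  The A-T stem unzips at an equilibrium force set by
`dg_bp = 2·g_nt(F)` (≈10 pN for the default parameters), compressing the
target through two ssDNA tethers.  A worm-like-chain target of bending
modulus `κ = l_p k_B T` resists compression up to the Euler threshold

    F_c = π²κ / h²   ⇔   h_b = π·√(κ/F)  =  14.5 nm (42.6 bp) at 9 pN,

so FRET vs `h` falls while the stem unzips and recovers once the target
buckles — a minimum near 40 bp for the large loops.  At high ionic
strength the model adds locally melted "kink" states (the meltable
worm-like chain): a bubble of `n` bp with persistence length `lp_melt`
acts as a nearly free hinge with free energy

    ΔG_kink = [n·dg_melt + σ_coop + U_bend(melt)] + ΔG_relax,

where the (negative) relaxation term collects duplex unbending, tether
relaxation and stem re-zipping.  When `ΔG_kink < 0` the transition moves
to ~30 bp, reproducing the buckling→kinking switch.  Details, parameter
defaults and calibration caveats are in [docs/methods.md](docs/methods.md).

## Worked example

Buckling length at the 9 pN A-T unzipping force:

```
$ visemech mech buckling --force 9
quantity        force_pN  value_nm            value_bp
buckling_length 9.0       14.484550593912745  42.601619393861014
```

A 64-bp minicircle relaxed by one flexible kink (the "teardrop", 71.2% of
the 42.2 k_BT circle energy — i.e. one kink releases ~12 k_BT):

```
$ visemech mech minicircle --bp 64 --kinks 1
quantity    bp  n_kinks  energy_kbt
minicircle  64  1        30.0347
```

Predicted FRET curve of the 46-nt loop around the buckling transition
(low salt, WLC ensemble) — the minimum sits at a 40-bp target:

```
$ visemech predict --loops 46 --targets 36:44 --out curves.tsv
$ grep -v "^#" curves.tsv | cut -f3,4
target_len  E
36          0.4705
37          0.3987
38          0.3536
39          0.3319
40          0.3292   <- buckling minimum
41          0.3404
42          0.3605
43          0.3847
44          0.4100
```

Kink free energy of the strained loop-36 / 34-bp construct under the
shipped 250 mM Na⁺ calibration — negative, so kinked states dominate,
with the gain split between duplex unbending, tether relaxation and stem
re-zipping:

```
$ visemech kink --loop 36 --target 34 --condition high-salt --breakdown
dG_kink         -5.073
dg_bubble_bp     9.510
dg_bubble_coop  18.629
dg_bubble_bend   2.624
dg_relax_ds     -9.271
dg_relax_ss    -12.082
dg_relax_stem  -14.483
```

Other subcommands: `fit-lp` (persistence-length fit to measured curves),
`saltscan` (transition metric across ionic conditions), `quantify`
(three-channel crosstalk-corrected FRET extraction), `mismatch`
(flexibility metric and exact Spearman rank test), `simulate`
(deterministic synthetic curves, band tables and mismatch panels).  The
same functionality is available as a library (`visemech.mechanics`,
`.ensemble`, `.mwlc`, `.saltmodel`, `.quantify`, `.synthdata`).

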