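# Parameter notes: Hill coefficients above 1

The default kinetic form is Michaelis (n = 1). Every steeper response in
the default network is listed here with its rationale; all values live in
`bmecsim/default_model.py`.

| reaction / regulator | n | K | rationale |
|---|---|---|---|
| `prod_ROS_RET`: ROS production vs succinate | 2 | 15 | reverse electron transport requires a high succinate load; baseline succinate (1) must contribute little while post-OGD loads (10–100) saturate the burst |
| `kp_IKK_ROS`: IKK activation by ROS | 2 | 3 | redox activation of IKK is burst-gated; baseline ROS must not inflame |
| `rel_Ca_ROS`: ER Ca²⁺ release by ROS | 2 | 3 | same burst gating |
| `kt_iNOS_ROS`: iNOS induction by ROS | 2 | 3 | same burst gating |
| `ox_BH4`: BH4 oxidation by ROS | 2 | 3 | same burst gating |
| `prod_ROS_BH2`: ROS from BH2 (eNOS uncoupling) | 2 | 0.6 | uncoupling grows superlinearly as the BH2 fraction rises |
| `deg_NRF2_Keap1`: ROS inactivation of Keap1 (inhibits NRF2 degradation) | 2 | 2.5 | cooperative cysteine oxidation of Keap1 |
| cytokine secretion vs nuclear NFκB | 2 | 0.25 | multiple κB sites per promoter; keeps basal secretion low and stimulated secretion strongly fold-responsive |
| A20 / IκB mRNA induction vs nuclear NFκB | 2 | 0.15 | as above, for the feedback genes |
| HIF target synthesis vs nuclear HIF | 2 | 0.6 | HRE cooperativity; limits basal leak |
| p53 induction terms (HIF: n=2 K=0.6; ROS: n=3 K=4) | 2–3 | — | stress-threshold activation; baseline ROS/HIF must not destabilize p53 |
| MDM2/TIGAR induction vs p53 | 2 | 1.5 | p53 tetramer binding |
| `kt_BAX` vs p53 | 3 | 2.0 | apoptotic genes respond only to sustained, high p53 |
| `kt_BAX_self`: BAX self-amplification | 6 | 2.5 | the commitment switch: steepness creates bistability so long-OGD latching and short-OGD reversibility coexist (see methods) |
| `kt_Casp3_BAX` | 4 | 3.2 | executioner activation above the mitochondrial permeabilization threshold |
| AMPK activation (AMP n=2 K=0.6; ATP inhibition n=2 K=0.5) | 2 | — | AMPK responds to the AMP/ATP *ratio*; paired opposing Hill terms approximate ratio sensing |
| `syn_ATP_aerobic`: ONOO⁻ inhibition | 4 | 1.3 | nitrosative inhibition of respiration is sharply thresholded; baseline ONOO⁻ (1) must leave respiration near-normal while the 4–6 h post-reox peak (~2–4) suppresses it, producing the delayed second AMPK peak |
| `eNOS` activation vs cytosolic Ca²⁺ | 2 | 0.3 | calmodulin cooperativity |
| `deg_ZO1_ROS` / `deg_Claudin5_ROS` vs ROS | 6 | 5.0 | junction damage is a burst-threshold event; with day-scale basal turnover the baseline ROS contribution must be ~10⁻⁵ h⁻¹ while burst ROS (≥4.5) degrades at ~0.3–0.5 h⁻¹ |
| same reactions, AKT_p inhibition | 2 | 0.1 | growth-factor (FGF/VEGF/Tie2) protection of junctions acts by suppressing ROS-driven degradation |
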