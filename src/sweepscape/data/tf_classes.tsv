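# TF class vocabulary: one label per line (tab-separated comment optional).
# The ten large named DNA-binding classes; extend freely with project labels.
KRAB-ZNF	C2H2 zinc finger with Kruppel-associated box
non-KRAB C2H2	C2H2 zinc finger without KRAB box
Homeo domain	homeobox DNA-binding domain
bHLH	basic helix-loop-helix
Forkhead	forkhead / winged helix box
High-mobility HMG	high-mobility-group domain
bZIP	basic leucine zipper
Nuclear receptor	ligand-regulated zinc-finger receptor
ETS	erythroblast-transformation-specific domain
T-box	T-box DNA-binding domain
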