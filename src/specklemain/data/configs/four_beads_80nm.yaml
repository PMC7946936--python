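# Four fluorescent beads (closest pair 80 nm), 500 speckle frames,
# 100x/1.5 oil detection, 65 nm camera pixels, blind-SIM at 3x upsampling
# (~22 nm reconstruction pixel).
scene_kind: bead_cluster
bead_diameter: 46.0

lambda_exc: 488.0
na_inc: 0.2
n_modes: 100
roughness_rms: 1.1
roughness_corr_length: 35.0
z_speckle: 10.0

na_det: 1.5
lambda_em: 520.0
camera_pixel: 65.0
n_camera_px: 20
dx_f: 5.0
n_frames: 500
photons_per_emitter: 5000.0
background: 5.0
read_sd: 2.0

upsample: 3
max_iter: 400
tol: 1.0e-6

master_seed: 1
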