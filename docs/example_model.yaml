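name: lower_body_torso
segments:
  pelvis:
    origin_in_parent:
    - 0.0
    - 0.0
    - 0.0
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.18
  torso:
    origin_in_parent:
    - 0.0
    - 0.0
    - 0.12
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.45
  femur_r:
    origin_in_parent:
    - 0.0
    - -0.09
    - 0.0
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.4
  femur_l:
    origin_in_parent:
    - 0.0
    - 0.09
    - 0.0
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.4
  tibia_r:
    origin_in_parent:
    - 0.0
    - 0.0
    - -0.4
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.4
  tibia_l:
    origin_in_parent:
    - 0.0
    - 0.0
    - -0.4
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.4
  calcn_r:
    origin_in_parent:
    - 0.0
    - 0.0
    - -0.4
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.2
  calcn_l:
    origin_in_parent:
    - 0.0
    - 0.0
    - -0.4
    offset_rot_quat:
    - 1.0
    - 0.0
    - 0.0
    - 0.0
    length: 0.2
joints:
- name: ground_pelvis
  kind: free6
  parent: ground
  child: pelvis
  axes:
  - coordinate: pelvis_tilt
    axis:
    - 0.0
    - 1.0
    - 0.0
  - coordinate: pelvis_list
    axis:
    - 1.0
    - 0.0
    - 0.0
  - coordinate: pelvis_rotation
    axis:
    - 0.0
    - 0.0
    - 1.0
  translations:
  - pelvis_tx
  - pelvis_ty
  - pelvis_tz
- name: back
  kind: ball3
  parent: pelvis
  child: torso
  axes:
  - coordinate: lumbar_extension
    axis:
    - 0.0
    - 1.0
    - 0.0
  - coordinate: lumbar_bending
    axis:
    - 1.0
    - 0.0
    - 0.0
  - coordinate: lumbar_rotation
    axis:
    - 0.0
    - 0.0
    - 1.0
  translations: []
- name: hip_r
  kind: ball3
  parent: pelvis
  child: femur_r
  axes:
  - coordinate: hip_flexion_r
    axis:
    - 0.0
    - 1.0
    - 0.0
  - coordinate: hip_adduction_r
    axis:
    - 1.0
    - 0.0
    - 0.0
  - coordinate: hip_rotation_r
    axis:
    - 0.0
    - 0.0
    - 1.0
  translations: []
- name: knee_r
  kind: pin1
  parent: femur_r
  child: tibia_r
  axes:
  - coordinate: knee_flexion_r
    axis:
    - 0.0
    - 1.0
    - 0.0
  translations: []
- name: ankle_r
  kind: pin1
  parent: tibia_r
  child: calcn_r
  axes:
  - coordinate: ankle_flexion_r
    axis:
    - 0.0
    - 1.0
    - 0.0
  translations: []
- name: hip_l
  kind: ball3
  parent: pelvis
  child: femur_l
  axes:
  - coordinate: hip_flexion_l
    axis:
    - 0.0
    - 1.0
    - 0.0
  - coordinate: hip_adduction_l
    axis:
    - 1.0
    - 0.0
    - 0.0
  - coordinate: hip_rotation_l
    axis:
    - 0.0
    - 0.0
    - 1.0
  translations: []
- name: knee_l
  kind: pin1
  parent: femur_l
  child: tibia_l
  axes:
  - coordinate: knee_flexion_l
    axis:
    - 0.0
    - 1.0
    - 0.0
  translations: []
- name: ankle_l
  kind: pin1
  parent: tibia_l
  child: calcn_l
  axes:
  - coordinate: ankle_flexion_l
    axis:
    - 0.0
    - 1.0
    - 0.0
  translations: []
imu_sites:
  torso_imu:
    segment: torso
    position:
    - 0.0
    - 0.0
    - 0.3
  pelvis_imu:
    segment: pelvis
    position:
    - -0.08
    - 0.0
    - 0.05
  femur_r_imu:
    segment: femur_r
    position:
    - 0.05
    - 0.0
    - -0.2
  femur_l_imu:
    segment: femur_l
    position:
    - 0.05
    - 0.0
    - -0.2
  tibia_r_imu:
    segment: tibia_r
    position:
    - 0.03
    - 0.0
    - -0.2
  tibia_l_imu:
    segment: tibia_l
    position:
    - 0.03
    - 0.0
    - -0.2
  calcn_r_imu:
    segment: calcn_r
    position:
    - 0.08
    - 0.0
    - 0.03
  calcn_l_imu:
    segment: calcn_l
    position:
    - 0.08
    - 0.0
    - 0.03
bounds_deg:
  pelvis_tilt:
  - -90.0
  - 90.0
  pelvis_list:
  - -90.0
  - 90.0
  pelvis_rotation:
  - -100000.0
  - 100000.0
  lumbar_extension:
  - -90.0
  - 90.0
  lumbar_bending:
  - -90.0
  - 90.0
  lumbar_rotation:
  - -90.0
  - 90.0
  hip_flexion_r:
  - -119.99999999999999
  - 119.99999999999999
  hip_adduction_r:
  - -59.99999999999999
  - 59.99999999999999
  hip_rotation_r:
  - -59.99999999999999
  - 59.99999999999999
  knee_flexion_r:
  - 0.0
  - 140.0
  ankle_flexion_r:
  - -59.99999999999999
  - 59.99999999999999
  hip_flexion_l:
  - -119.99999999999999
  - 119.99999999999999
  hip_adduction_l:
  - -59.99999999999999
  - 59.99999999999999
  hip_rotation_l:
  - -59.99999999999999
  - 59.99999999999999
  knee_flexion_l:
  - 0.0
  - 140.0
  ankle_flexion_l:
  - -59.99999999999999
  - 59.99999999999999
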