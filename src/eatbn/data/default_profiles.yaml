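# Default activity emission profiles and context-truth table for the
# synthetic sensor-stream simulator.
#
# Channels: wrist accelerometer h_acc_{x,y,z} (m/s^2, 20 Hz), wrist
# illuminometer h_lux (lux, 1 Hz), thermometer h_temp (degC, 1 Hz),
# hygrometer h_hum (g/m^3, 1 Hz), phone accelerometer acc_{x,y,z}
# (m/s^2, 20 Hz).
#
# Per channel: mean, sd (Gaussian noise), and an optional sinusoid
# (amp, period in seconds) modeling repetitive motion — the hand-to-mouth
# cycle while eating, stride while walking, vehicle vibration.
#
# true_contexts lists the low-level context properties that hold ("true")
# during the activity; all other properties are "false".  Higher context
# nodes are derived from these by majority (see eatbn.simulate).

base_emissions:
  h_acc_x: {mean: 0.0, sd: 0.3}
  h_acc_y: {mean: 0.0, sd: 0.3}
  h_acc_z: {mean: 9.8, sd: 0.3}
  h_lux:   {mean: 300.0, sd: 30.0}
  h_temp:  {mean: 29.0, sd: 0.5}
  h_hum:   {mean: 11.0, sd: 0.5}
  acc_x:   {mean: 0.0, sd: 0.1}
  acc_y:   {mean: 0.0, sd: 0.1}
  acc_z:   {mean: 9.8, sd: 0.1}

activities:
  1:
    name: washing
    true_contexts: [movement_of_hand, humidity_of_hand, indoor_outdoor,
                    move_stop_spatial, illuminance_of_space]
    emissions:
      h_acc_x: {mean: 0.5, sd: 1.5, amp: 1.0, period: 0.8}
      h_acc_y: {mean: 0.3, sd: 1.5, amp: 1.0, period: 0.8}
      h_acc_z: {mean: 9.0, sd: 1.2}
      h_hum:   {mean: 16.0, sd: 1.0}
      h_lux:   {mean: 350.0, sd: 40.0}
  2:
    name: walking
    true_contexts: [body_temperature]
    emissions:
      h_acc_x: {mean: 0.5, sd: 1.2, amp: 3.0, period: 0.55}
      h_acc_y: {mean: 0.5, sd: 1.2, amp: 3.0, period: 0.55}
      h_acc_z: {mean: 9.5, sd: 1.2, amp: 2.0, period: 0.55}
      h_lux:   {mean: 5000.0, sd: 800.0}
      h_temp:  {mean: 22.0, sd: 1.0}
      h_hum:   {mean: 9.0, sd: 0.8}
      acc_x:   {mean: 0.3, sd: 1.0, amp: 2.5, period: 0.55}
      acc_y:   {mean: 0.3, sd: 1.0, amp: 2.5, period: 0.55}
      acc_z:   {mean: 9.5, sd: 1.0, amp: 1.5, period: 0.55}
  3:
    name: housework
    true_contexts: [movement_of_hand, indoor_outdoor, illuminance_of_space,
                    eating_time]
    emissions:
      h_acc_x: {mean: 1.0, sd: 2.0}
      h_acc_y: {mean: 0.8, sd: 2.0}
      h_acc_z: {mean: 8.8, sd: 1.8}
      h_lux:   {mean: 320.0, sd: 40.0}
      acc_x:   {mean: 0.2, sd: 0.8}
      acc_y:   {mean: 0.2, sd: 0.8}
      acc_z:   {mean: 9.7, sd: 0.8}
  4:
    name: eating_dinnerware
    true_contexts: [position_of_hand, dinnerware, movement_of_hand,
                    posture_body, move_stop_body, movement_of_body,
                    body_temperature, posture_operation, humidity_of_hand,
                    existence_of_food, eating_place, indoor_outdoor,
                    move_stop_spatial, illuminance_of_space, eating_time]
    emissions:
      h_acc_x: {mean: 3.0, sd: 0.8, amp: 1.2, period: 3.0}
      h_acc_y: {mean: 1.5, sd: 0.8, amp: 2.5, period: 3.0}
      h_acc_z: {mean: 8.5, sd: 0.8, amp: 1.0, period: 3.0}
      h_lux:   {mean: 330.0, sd: 25.0}
      h_temp:  {mean: 31.0, sd: 0.5}
      h_hum:   {mean: 14.0, sd: 0.6}
      acc_x:   {mean: 0.0, sd: 0.05}
      acc_y:   {mean: 0.0, sd: 0.05}
      acc_z:   {mean: 9.8, sd: 0.05}
  5:
    name: eating_etc
    true_contexts: [position_of_hand, movement_of_hand,
                    posture_body, move_stop_body, movement_of_body,
                    body_temperature, posture_operation, humidity_of_hand,
                    existence_of_food, eating_place, indoor_outdoor,
                    move_stop_spatial, illuminance_of_space, eating_time]
    emissions:
      h_acc_x: {mean: 1.2, sd: 0.4, amp: 0.5, period: 4.0}
      h_acc_y: {mean: 1.8, sd: 0.4, amp: 1.2, period: 4.0}
      h_acc_z: {mean: 9.0, sd: 0.4}
      h_lux:   {mean: 400.0, sd: 60.0}
      h_temp:  {mean: 30.5, sd: 0.5}
      h_hum:   {mean: 13.0, sd: 0.6}
      acc_x:   {mean: 0.0, sd: 0.05}
      acc_y:   {mean: 0.0, sd: 0.05}
      acc_z:   {mean: 9.8, sd: 0.05}
  6:
    name: conversation
    true_contexts: [posture_body, move_stop_body, body_temperature,
                    posture_operation, eating_place, indoor_outdoor,
                    move_stop_spatial, illuminance_of_space, eating_time]
    emissions:
      h_acc_x: {mean: 0.3, sd: 0.6}
      h_acc_y: {mean: 0.3, sd: 0.6}
      h_acc_z: {mean: 9.6, sd: 0.5}
  7:
    name: driving
    true_contexts: [posture_body, move_stop_body, body_temperature]
    emissions:
      h_acc_x: {mean: 0.3, sd: 0.5, amp: 0.3, period: 0.1}
      h_acc_y: {mean: 0.2, sd: 0.5, amp: 0.3, period: 0.1}
      h_acc_z: {mean: 9.7, sd: 0.5}
      h_lux:   {mean: 900.0, sd: 150.0}
      h_temp:  {mean: 25.0, sd: 0.8}
      acc_x:   {mean: 0.1, sd: 0.4, amp: 0.3, period: 0.1}
      acc_y:   {mean: 0.1, sd: 0.4, amp: 0.3, period: 0.1}
      acc_z:   {mean: 9.8, sd: 0.4, amp: 0.3, period: 0.1}
  8:
    name: sedentary_work
    true_contexts: [posture_body, move_stop_body, movement_of_body,
                    body_temperature, posture_operation, eating_place,
                    indoor_outdoor, move_stop_spatial, illuminance_of_space,
                    eating_time]
    emissions:
      h_acc_x: {mean: 0.4, sd: 0.4}
      h_acc_y: {mean: 0.2, sd: 0.4}
      h_acc_z: {mean: 9.7, sd: 0.3}
      h_lux:   {mean: 350.0, sd: 30.0}
  9:
    name: subway
    true_contexts: [posture_body, body_temperature]
    emissions:
      h_acc_x: {mean: 0.2, sd: 0.6, amp: 0.4, period: 0.15}
      h_acc_y: {mean: 0.2, sd: 0.6, amp: 0.4, period: 0.15}
      h_acc_z: {mean: 9.7, sd: 0.6}
      h_lux:   {mean: 250.0, sd: 30.0}
      h_temp:  {mean: 26.0, sd: 0.8}
      acc_x:   {mean: 0.1, sd: 0.5, amp: 0.4, period: 0.15}
      acc_y:   {mean: 0.1, sd: 0.5, amp: 0.4, period: 0.15}
      acc_z:   {mean: 9.8, sd: 0.5}
  10:
    name: playing_piano
    true_contexts: [movement_of_hand, posture_body, move_stop_body,
                    move_stop_spatial, indoor_outdoor, illuminance_of_space,
                    eating_time]
    emissions:
      h_acc_x: {mean: 0.8, sd: 1.8, amp: 1.5, period: 0.5}
      h_acc_y: {mean: 0.5, sd: 1.8, amp: 1.5, period: 0.5}
      h_acc_z: {mean: 9.3, sd: 1.5}
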