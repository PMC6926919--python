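age_group,location,hours,eec
infant,home,21.38,71.4
infant,indoors_away,1.17,15.2
infant,outdoors,0.95,6
infant,vehicle,0.50,6
young_child,home,17.73,71.4
young_child,indoors_away,3.67,71.4
young_child,outdoors,1.82,6
young_child,vehicle,0.78,6
child,home,17.12,71.4
child,indoors_away,4.27,24.4
child,outdoors,1.80,6
child,vehicle,0.81,6
adolescent,home,16.67,71.4
adolescent,indoors_away,4.98,24.2
adolescent,outdoors,1.48,6
adolescent,vehicle,0.87,6
adult,home,16.03,71.4
adult,indoors_away,5.13,15.2
adult,outdoors,1.32,6
adult,vehicle,1.52,6
senior,home,18.63,71.4
senior,indoors_away,2.98,15.2
senior,outdoors,1.32,6
senior,vehicle,1.07,6
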