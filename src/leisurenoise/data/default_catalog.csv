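activity_id,label,laeq_max
band,Playing in a band,105
classical_concert,Listening to classical music,105
arcade,Video arcades,100
stereo_speakers,Home stereo through loudspeakers,100
stereo_headphones,Home stereo through headphones,100
personal_stereo,Personal audio devices,100
motor_sport,Motor sport,105
disco,Discos and pop concerts,105
home_tools,Home power tools,105
shooting,Shooting,105
tv,Television watching,100
video_games,Video games at home,100
bars,Bars and pubs,105
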