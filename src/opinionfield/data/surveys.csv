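survey_id,label,text,yes_pct,no_pct
EU,a,"Thanks to scientific and technological advances, the Earth's natural resources will be inexhaustible.",21,56
EU,b,"Science and technology can sort out any problem.",22,57
EU,c,"Science and technology cannot really play a role in improving the environment.",24,54
EU,d,"Science should have no limits to what it is able to investigate.",35,44
EU,e,"We depend too much on science and not enough on faith.",38,34
EU,f,"Some numbers are especially lucky for some people.",40,35
EU,g,"Scientists should be allowed to experiment on animals like dogs and monkeys if this can help sort out human health problems.",44,37
EU,h,"The benefits of science are greater than any harmful effects it may have.",46,20
EU,i,"Because of their knowledge, scientists have a power that makes them dangerous.",53,24
EU,j,"Science makes our ways of life change too fast.",58,22
EU,k,"The application of science and new technologies will make people's work more interesting.",61,14
EU,l,"Compared with research carried out and funded by each Member State, to what extent do you think that collaborative research across Europe and funded by the European Union is in the national interest?",66,10
EU,m,"Even if it brings no immediate benefits, scientific research which adds to knowledge should be supported by Government.",72,9
EU,n,"Thanks to science and technology, there will be more opportunities for future generations.",75,8
EU,o,"A scientific discovery is in itself neither ""good"" nor ""bad"", it is only the way the discovery is used which matters.",78,7
Mx,a,"Thanks to scientific and technological advances, the Earth's natural resources will be inexhaustible.",33,63
Mx,b,"Science and technology can sort out any problem.",21,76
Mx,c,"Science and technology cannot really play a role in improving the environment.",15,81
Mx,d,"Science should have no limits to what it is able to investigate.",70,17
Mx,e,"We depend too much on science and not enough on faith.",16,84
Mx,f,"Some numbers are especially lucky for some people.",34,64
Mx,g,"Scientists should be allowed to experiment on animals like dogs and monkeys if this can help sort out human health problems.",57,41
Mx,h,"The benefits of science are greater than any harmful effects it may have.",69,23
Mx,i,"Because of their knowledge, scientists have a power that makes them dangerous.",57,39
Mx,j,"Science makes our ways of life change too fast.",83,14
Mx,k,"The application of science and new technologies will make people's work more interesting.",81,15
Mx,l,"Compared with research carried out and funded by each Member State, to what extent do you think that collaborative research across Europe and funded by the European Union is in the national interest?",94,3
Mx,m,"Even if it brings no immediate benefits, scientific research which adds to knowledge should be supported by Government.",88,9
Mx,n,"Thanks to science and technology, there will be more opportunities for future generations.",88,9
Mx,o,"A scientific discovery is in itself neither ""good"" nor ""bad"", it is only the way the discovery is used which matters.",91,6
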