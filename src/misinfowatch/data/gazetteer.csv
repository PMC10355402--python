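term,country
US,US
USA,US
United States,US
United States of America,US
America,US
New York,US
NYC,US
California,US
Los Angeles,US
Texas,US
Houston,US
Florida,US
Chicago,US
Illinois,US
Washington DC,US
Seattle,US
Boston,US
Atlanta,US
Georgia,US
Pennsylvania,US
Philadelphia,US
Arizona,US
Ohio,US
Michigan,US
San Francisco,US
UK,UK
United Kingdom,UK
Britain,UK
Great Britain,UK
England,UK
Scotland,UK
Wales,UK
Northern Ireland,UK
London,UK
Manchester,UK
Birmingham,UK
Liverpool,UK
Leeds,UK
Glasgow,UK
Edinburgh,UK
Bristol,UK
India,India
Mumbai,India
Delhi,India
New Delhi,India
Bangalore,India
Bengaluru,India
Chennai,India
Kolkata,India
Hyderabad,India
Maharashtra,India
Pune,India
Canada,Canada
Toronto,Canada
Ontario,Canada
Montreal,Canada
Quebec,Canada
Vancouver,Canada
British Columbia,Canada
Alberta,Canada
Calgary,Canada
Ottawa,Canada
Winnipeg,Canada
Australia,Australia
Sydney,Australia
Melbourne,Australia
Brisbane,Australia
Perth,Australia
Adelaide,Australia
Queensland,Australia
Victoria,Australia
New South Wales,Australia
Canberra,Australia
Nigeria,Nigeria
Lagos,Nigeria
Abuja,Nigeria
Kano,Nigeria
Ibadan,Nigeria
Port Harcourt,Nigeria
Ireland,Ireland
Dublin,Ireland
Cork,Ireland
Galway,Ireland
Limerick,Ireland
South Africa,South Africa
Johannesburg,South Africa
Cape Town,South Africa
Durban,South Africa
Pretoria,South Africa
Gauteng,South Africa
France,France
Paris,France
Lyon,France
Marseille,France
Toulouse,France
Bordeaux,France
Japan,Japan
Tokyo,Japan
Osaka,Japan
Kyoto,Japan
Yokohama,Japan
South Korea,South Korea
Seoul,South Korea
Busan,South Korea
Incheon,South Korea
Singapore,Singapore
Spain,Spain
Madrid,Spain
Barcelona,Spain
Valencia,Spain
Seville,Spain
Netherlands,Netherlands
Amsterdam,Netherlands
Rotterdam,Netherlands
The Hague,Netherlands
Utrecht,Netherlands
Ukraine,Ukraine
Kyiv,Ukraine
Kiev,Ukraine
Kharkiv,Ukraine
Odesa,Ukraine
Germany,Germany
Berlin,Germany
Munich,Germany
Hamburg,Germany
Frankfurt,Germany
Cologne,Germany
Georgia,Georgia
Tbilisi,Georgia
Batumi,Georgia
Victoria,Canada
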